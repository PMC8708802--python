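"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import product
from typing import Dict, List, Tuple

import numpy as np
import pytest

from dicationmsi.adducts import load_headgroup_rules, load_reagent
from dicationmsi.chem import default_table
from dicationmsi.msi import load_library
from dicationmsi.simulate import SimulationConfig, default_mask


@pytest.fixture(scope="session")
def reagent():
    return load_reagent()


@pytest.fixture(scope="session")
def rules():
    return load_headgroup_rules()


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def isotope_table():
    return default_table()


@pytest.fixture()
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture()
def roi_mask(sim_config):
    return default_mask(sim_config)


# ---------------------------------------------------------------------------
# Independent oracle: brute-force isotopologue enumeration
# ---------------------------------------------------------------------------


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def brute_force_pattern(formula, table=None, n_peaks: int = 3) -> List[Tuple[float, float]]:
    """Exact aggregated isotope pattern by enumerating every isotopologue.

    Independent of the convolution implementation: multinomial abundance of
    each per-element isotope-count vector, exact mass offsets, binned by
    nucleon-count offset. Practical for formulas with <= ~30 atoms.
    """
    table = table or default_table()
    # per element: list of (offset_bins, mass_offsets, abundances)
    per_element = []
    for elem, n in formula.items():
        rows = table.isotopes[elem]
        mono = table.principal_mass(elem)
        options: Dict[int, Tuple[float, float]] = {}  # vector -> (ab, moff)
        combos = []
        for vec in _compositions(n, len(rows)):
            coef = math.factorial(n)
            ab = 1.0
            moff = 0.0
            koff = 0
            for c, (mass, a) in zip(vec, rows):
                coef //= math.factorial(c)
                ab *= a**c
                moff += c * (mass - mono)
                koff += c * (round(mass) - round(mono))
            combos.append((koff, coef * ab, moff))
        per_element.append(combos)

    bins: Dict[int, List[float]] = {}
    for combo in product(*per_element):
        koff = sum(c[0] for c in combo)
        ab = 1.0
        moff = 0.0
        for k, a, m in combo:
            ab *= a
            moff += m
        if koff >= n_peaks:
            continue
        acc = bins.setdefault(koff, [0.0, 0.0])
        acc[0] += ab
        acc[1] += ab * moff
    base = max(acc[0] for acc in bins.values())
    out = []
    for k in range(n_peaks):
        if k in bins:
            ab, wsum = bins[k]
            out.append((wsum / ab, ab / base))
        else:
            out.append((k * 1.003355, 0.0))
    return out


@pytest.fixture(scope="session")
def brute_pattern():
    return brute_force_pattern
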