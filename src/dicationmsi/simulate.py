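"""Ground-truthed synthetic MSI datasets and MS/MS spectra.

Emulates the acquisition designs the pipeline is meant for: a
quasi-homogeneous tissue region of 20×20 on-tissue pixels next to a 10×10
off-tissue block at 150 µm pitch, acquired in three modes (negative,
positive, dication-adducted positive), with per-peak ppm-scale mass jitter,
lognormal abundance noise, isotope envelopes, uniform solvent background
ions planted equally on and off tissue, and — in the adducted mode —
reagent-derived solvent peaks in every pixel. Imaging tests use a two-blob
("follicle-like") spatial pattern.

Every simulated non-background peak traces back to a species + ion label in
the returned truth table, so recovery by the pipeline can be scored
exactly. All randomness flows through a single seeded generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adducts import ReagentDefinition, adduct_mz, load_reagent, predict_fragments
from .chem import (
    PROTON_MASS,
    ElementalFormula,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
)
from .msi import (
    LABEL_DEPROTONATED,
    LABEL_PROTONATED,
    MsiDataset,
    RoiMask,
    adduct_label,
    load_library,
)

__all__ = [
    "GroundTruthSpecies",
    "SimulationConfig",
    "RAT_LIVER_WINDOWS",
    "HEN_OVARY_WINDOWS",
    "default_mask",
    "default_truth",
    "two_blob_truth",
    "simulate_msi",
    "simulate_msms",
    "truth_to_frame",
]

#: The two acquisition windows used per condition on rat liver sections.
RAT_LIVER_WINDOWS = ((150.0, 600.0), (450.0, 1800.0))

#: Per-mode windows used for hen ovary imaging.
HEN_OVARY_WINDOWS = {
    "negative": (200.0, 1000.0),
    "positive": (350.0, 1400.0),
    "adducted_positive": (350.0, 1400.0),
}


@dataclass(frozen=True)
class GroundTruthSpecies:
    """A planted metabolite with its detectability and spatial pattern.

    ``polarity_class`` says how the molecule ionizes: ``anionic`` species
    deprotonate (negative mode) and pair with the dication in the adducted
    run; ``cationic`` species protonate and appear at their usual m/z in
    both positive runs. ``spatial_pattern`` is ``"uniform"`` or a tuple of
    ``(cx, cy, radius)`` discs ("blobs") in pixel coordinates.
    """

    name: str
    formula: ElementalFormula
    lipid_class: str
    polarity_class: str
    detectable_modes: FrozenSet[str]
    spatial_pattern: object = "uniform"
    base_abundance: float = 1e5

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if self.polarity_class not in ("anionic", "cationic"):
            raise ValueError("polarity_class must be anionic or cationic")
        if self.polarity_class == "anionic" and "adducted_positive" not in self.detectable_modes:
            raise ValueError("anionic (adduct-forming) species must list adducted_positive")

    def ion_label(self, mode: str, reagent: Optional[ReagentDefinition] = None) -> str:
        if mode == "negative":
            return LABEL_DEPROTONATED
        if mode == "positive":
            return LABEL_PROTONATED
        if self.polarity_class == "anionic":
            return adduct_label(reagent)
        return LABEL_PROTONATED

    def ion_mz_in(self, mode: str, reagent: Optional[ReagentDefinition] = None) -> float:
        label = self.ion_label(mode, reagent)
        mass = monoisotopic_mass(self.formula)
        if label == LABEL_DEPROTONATED:
            return mass - PROTON_MASS
        if label == LABEL_PROTONATED:
            return mass + PROTON_MASS
        return adduct_mz(self.formula, reagent)

    def ion_composition(self, mode: str, reagent: Optional[ReagentDefinition] = None):
        label = self.ion_label(mode, reagent)
        H = parse_formula("H")
        if label == LABEL_DEPROTONATED:
            return self.formula - H
        if label == LABEL_PROTONATED:
            return self.formula + H
        reagent = reagent or load_reagent()
        return self.formula - H + reagent.dication_formula

    def pattern_weight(self, x: int, y: int) -> float:
        if self.spatial_pattern == "uniform":
            return 1.0
        for cx, cy, r in self.spatial_pattern:
            if (x - cx) ** 2 + (y - cy) ** 2 <= r**2:
                return 1.0
        return 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition geometry, noise model and instrument emulation knobs.

    The grid is 30×20: a 20×20 on-tissue block at the origin, a 10×10
    off-tissue block at x≥20, and a background-only remainder (scanned but
    in neither ROI). Each condition was acquired over two m/z windows
    (150–600 and 450–1800 for the development tissue); one simulated
    dataset stands for the merged acquisition, so the default per-mode
    window is their union. Mass jitter is Gaussian in ppm (default 1.0,
    appropriate for a 240k-resolution instrument inside a ±2.5 ppm match
    gate); abundance noise is lognormal with the given CV.
    """

    grid: Tuple[int, int] = (30, 20)
    on_origin: Tuple[int, int] = (0, 0)
    on_shape: Tuple[int, int] = (20, 20)
    off_origin: Tuple[int, int] = (20, 0)
    off_shape: Tuple[int, int] = (10, 10)
    pixel_pitch_um: float = 150.0
    mz_windows: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "negative": (150.0, 1800.0),
            "positive": (150.0, 1800.0),
            "adducted_positive": (150.0, 1800.0),
        }
    )
    mass_jitter_ppm: float = 1.0
    abundance_noise_cv: float = 0.2
    n_background: int = 10
    background_intensity: float = 5e4
    reagent_intensity: float = 5e6
    isotope_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_jitter_ppm < 0 or self.abundance_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.isotope_depth < 0:
            raise ValueError("isotope_depth must be >= 0")


def default_mask(config: Optional[SimulationConfig] = None) -> RoiMask:
    config = config or SimulationConfig()
    return RoiMask.from_rectangles(
        config.on_origin, config.on_shape, config.off_origin, config.off_shape
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def default_truth(
    n_adduct: int = 20,
    n_positive: int = 30,
    n_shared_negative: int = 15,
    seed: int = 0,
    library: Optional[pd.DataFrame] = None,
) -> List[GroundTruthSpecies]:
    """Draw a ground-truth species set from the bundled library.

    ``n_adduct`` anionic adduct-formers (class mix weighted toward fatty
    acids, with some PAs/PEs/PIs), of which ``n_shared_negative`` are also
    detectable in negative mode; ``n_positive`` cationic species detectable
    in positive mode and retained at their usual m/z in the adducted run.
    Reproducible per seed.
    """
    if min(n_adduct, n_positive, n_shared_negative) < 0:
        raise ValueError("counts must be non-negative")
    if n_shared_negative > n_adduct:
        raise ValueError("n_shared_negative cannot exceed n_adduct")
    rng = np.random.default_rng(seed)
    lib = library if library is not None else load_library()

    anionic = lib[lib.expected_polarity.isin(["negative", "both"])]
    cationic = lib[lib.expected_polarity.isin(["positive", "both"])]

    class_weight = {"FA": 4.0, "PA": 1.0, "PE": 1.0, "PI": 1.0}
    w = np.array([class_weight.get(c, 1.0) for c in anionic.lipid_class], float)
    if n_adduct > len(anionic):
        raise ValueError("not enough anionic library entries")
    idx_a = rng.choice(len(anionic), size=n_adduct, replace=False, p=w / w.sum())
    chosen_a = anionic.iloc[sorted(idx_a)]

    cat_pool = cationic[~cationic.name.isin(chosen_a.name)]
    if n_positive > len(cat_pool):
        raise ValueError("not enough cationic library entries")
    idx_c = rng.choice(len(cat_pool), size=n_positive, replace=False)
    chosen_c = cat_pool.iloc[sorted(idx_c)]

    shared = set(rng.choice(n_adduct, size=n_shared_negative, replace=False).tolist())

    truth: List[GroundTruthSpecies] = []
    for i, row in enumerate(chosen_a.itertuples(index=False)):
        modes = {"adducted_positive"}
        if i in shared:
            modes.add("negative")
        truth.append(
            GroundTruthSpecies(
                name=row.name,
                formula=parse_formula(row.formula),
                lipid_class=row.lipid_class,
                polarity_class="anionic",
                detectable_modes=frozenset(modes),
                base_abundance=float(1e5 * _lognormal_factor(rng, 0.5)),
            )
        )
    for row in chosen_c.itertuples(index=False):
        truth.append(
            GroundTruthSpecies(
                name=row.name,
                formula=parse_formula(row.formula),
                lipid_class=row.lipid_class,
                polarity_class="cationic",
                detectable_modes=frozenset({"positive", "adducted_positive"}),
                base_abundance=float(1e5 * _lognormal_factor(rng, 0.5)),
            )
        )
    return truth


def two_blob_truth(
    truth: Sequence[GroundTruthSpecies],
    blobs: Tuple[Tuple[int, int, int], ...] = ((5, 6, 3), (13, 12, 4)),
    every: int = 4,
) -> List[GroundTruthSpecies]:
    """Give every ``every``-th species a two-disc "follicle" pattern."""
    out = []
    for i, sp in enumerate(truth):
        if i % every == 0:
            out.append(replace(sp, spatial_pattern=blobs))
        else:
            out.append(sp)
    return out


def simulate_msi(
    truth: Sequence[GroundTruthSpecies],
    mode: str,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    reagent: Optional[ReagentDefinition] = None,
) -> Tuple[MsiDataset, pd.DataFrame]:
    """Simulate one acquisition and return (dataset, truth table).

    Species detectable in ``mode`` appear in on-tissue pixels at their
    mode-appropriate ion m/z (jittered per peak), with M+1..M+k isotope
    companions at theoretical relative abundances. Background ions are
    drawn uniformly over the m/z window and planted on *and* off tissue at
    equal mean intensity (so the on/off ≥1.5× filter removes them by
    construction). In the adducted mode the reagent dication and its
    counterion pair appear in every pixel. Species whose ion falls outside
    the window are omitted with a warning row in the truth table.
    """
    if mode not in ("negative", "positive", "adducted_positive"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or SimulationConfig()
    reagent = reagent or load_reagent()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.mz_windows[mode]
    nx, ny = config.grid
    mask = default_mask(config)
    n_iso = config.isotope_depth + 1

    # Per-species precomputation: ion m/z, label, isotope envelope.
    active = []
    truth_rows = []
    for sp in truth:
        if mode not in sp.detectable_modes:
            continue
        mz0 = sp.ion_mz_in(mode, reagent)
        label = sp.ion_label(mode, reagent)
        pattern = isotope_pattern(sp.ion_composition(mode, reagent), n_peaks=max(n_iso, 2))
        in_window = lo <= mz0 <= hi
        for k, (off, rel) in enumerate(pattern[:n_iso]):
            truth_rows.append(
                {
                    "species": sp.name,
                    "formula": str(sp.formula),
                    "lipid_class": sp.lipid_class,
                    "role": "species",
                    "ion_label": label,
                    "isotope": k,
                    "mz": mz0 + off,
                    "relative_abundance": rel,
                    "base_abundance": sp.base_abundance,
                    "pattern": "uniform" if sp.spatial_pattern == "uniform" else "blobs",
                    "in_window": in_window and lo <= mz0 + off <= hi,
                }
            )
        if not in_window:
            warnings.warn(f"{sp.name} ion at {mz0:.4f} outside window [{lo},{hi}]; omitted")
            continue
        active.append((sp, mz0, [(o, r) for o, r in pattern[:n_iso]]))

    # Background ions: uniform over the window, equal on/off intensity.
    bg_mz = np.sort(rng.uniform(lo, hi, size=config.n_background))
    bg_base = config.background_intensity * _lognormal_factor(rng, 0.3, size=config.n_background)
    for mzb, ib in zip(bg_mz, bg_base):
        truth_rows.append(
            {
                "species": "background",
                "formula": "",
                "lipid_class": "",
                "role": "background",
                "ion_label": "",
                "isotope": 0,
                "mz": float(mzb),
                "relative_abundance": 1.0,
                "base_abundance": float(ib),
                "pattern": "everywhere",
                "in_window": True,
            }
        )

    reagent_peaks: List[Tuple[float, float]] = []
    if mode == "adducted_positive":
        for mzr, lbl in (
            (reagent.dication_mz, "dication z=2"),
            (reagent.ion_pair_mz, "ion pair z=1"),
        ):
            if lo <= mzr <= hi:
                reagent_peaks.append((mzr, config.reagent_intensity))
                truth_rows.append(
                    {
                        "species": "reagent",
                        "formula": str(reagent.dication_formula),
                        "lipid_class": "",
                        "role": "reagent",
                        "ion_label": lbl,
                        "isotope": 0,
                        "mz": mzr,
                        "relative_abundance": 1.0,
                        "base_abundance": config.reagent_intensity,
                        "pattern": "everywhere",
                        "in_window": True,
                    }
                )

    jitter = config.mass_jitter_ppm * 1e-6
    cv = config.abundance_noise_cv
    spectra: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}
    on = mask.on_tissue
    for y in range(ny):
        for x in range(nx):
            mzs: List[float] = []
            ints: List[float] = []
            if (x, y) in on:
                for sp, mz0, pattern in active:
                    w = sp.pattern_weight(x, y)
                    if w <= 0:
                        continue
                    scale = sp.base_abundance * w * _lognormal_factor(rng, cv)
                    for off, rel in pattern:
                        mzk = mz0 + off
                        if not (lo <= mzk <= hi):
                            continue
                        mzs.append(mzk * (1.0 + rng.normal(0.0, jitter) if jitter else 1.0))
                        ints.append(scale * rel)
            for mzb, ib in zip(bg_mz, bg_base):
                mzs.append(float(mzb) * (1.0 + rng.normal(0.0, jitter) if jitter else 1.0))
                ints.append(float(ib) * _lognormal_factor(rng, cv))
            for mzr, ir in reagent_peaks:
                mzs.append(mzr * (1.0 + rng.normal(0.0, jitter) if jitter else 1.0))
                ints.append(ir * _lognormal_factor(rng, cv))
            order = np.argsort(mzs, kind="stable")
            spectra[(x, y)] = (
                np.asarray(mzs, dtype=np.float64)[order],
                np.asarray(ints, dtype=np.float64)[order],
            )

    dataset = MsiDataset(
        shape=(nx, ny),
        spectra=spectra,
        polarity=mode,
        mz_window=(lo, hi),
        pixel_pitch_um=config.pixel_pitch_um,
    )
    return dataset, truth_to_frame(truth_rows)


def truth_to_frame(rows: List[dict]) -> pd.DataFrame:
    cols = [
        "species",
        "formula",
        "lipid_class",
        "role",
        "ion_label",
        "isotope",
        "mz",
        "relative_abundance",
        "base_abundance",
        "pattern",
        "in_window",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_msms(
    metabolite,
    lipid_class: str,
    reagent: Optional[ReagentDefinition] = None,
    seed: int = 0,
    *,
    n_noise_peaks: int = 0,
    noise_intensity: float = 0.1,
    abundance_noise_cv: float = 0.0,
    drop_precursor_loss: bool = False,
) -> List[Tuple[float, float]]:
    """Simulate an HCD MS/MS spectrum of a dication adduct.

    Contains every predicted fragment at class-typical relative abundances
    (reagent fragment as base peak), optionally dropping the precursor-loss
    fragment to emulate a low-abundance precursor, plus ``n_noise_peaks``
    uniform-random noise peaks at ``noise_intensity`` relative abundance.
    """
    reagent = reagent or load_reagent()
    rng = np.random.default_rng(seed)
    f = metabolite if isinstance(metabolite, ElementalFormula) else parse_formula(metabolite)
    preds = predict_fragments(f, lipid_class, reagent)
    base_by_rule = {
        "reagent fragment": 1.0,
        "generic neutral loss": 0.6,
        "headgroup": 0.8,
        "headgroup secondary loss": 0.3,
    }
    peaks: List[Tuple[float, float]] = []
    for p in preds:
        if drop_precursor_loss and p.rule.startswith("generic neutral loss"):
            continue
        base = 0.5
        for rule, b in base_by_rule.items():
            if p.rule.startswith(rule):
                base = b
        peaks.append((p.mz, base * float(_lognormal_factor(rng, abundance_noise_cv))))
    precursor = adduct_mz(f, reagent)
    for _ in range(n_noise_peaks):
        peaks.append(
            (float(rng.uniform(100.0, precursor)), noise_intensity * float(rng.uniform(0.5, 1.5)))
        )
    peaks.sort()
    return peaks
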