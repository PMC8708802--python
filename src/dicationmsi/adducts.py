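"""Dication ion-pairing reagent model: adduct and fragment m/z prediction.

A dicationic pairing reagent (default: the 1,5-pentanediyl-
bis(1-butylpyrrolidinium) dication, C21H44N2 2+, delivered as the
difluoride salt) binds a singly deprotonated metabolite [M−H]− to give a
net +1 adduct [M−H+R]+ observable in positive mode. Annotation therefore
reduces to a constant mass shift: the dication mass (monoisotopic minus
two electrons, 324.3494 Da for the default reagent).

Under HCD the adducts fragment characteristically:

* generic neutral loss of a butylpyrrolidine arm (C8H17N, 127.1361 Da)
  from the precursor;
* a reagent-derived fragment ion (C13H26N+, m/z 196.2060) in every
  spectrum;
* for glycerophospholipids, the reagent stays paired with the polar
  headgroup: [headgroup anion + R − C8H17N]+ (e.g. dihydrogen phosphate
  for PA, phosphoethanolamine for PE, inositol monophosphate for PI);
* PE's headgroup fragment loses a further C2H5N (43.0422 Da).

Headgroup rules and reagent definitions are data (packaged TSV tables),
editable to explore other reagents or lipid classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import (
    ELECTRON_MASS,
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "ReagentDefinition",
    "HeadgroupRule",
    "FragmentPrediction",
    "MsmsValidation",
    "load_reagent",
    "load_headgroup_rules",
    "dication_shift",
    "adduct_mz",
    "anion_mz",
    "strip_shift",
    "predict_fragments",
    "fragments_to_frame",
    "match_msms",
]


@dataclass(frozen=True)
class ReagentDefinition:
    """A dicationic pairing reagent and its fragmentation bookkeeping."""

    name: str
    dication_formula: ElementalFormula
    dication_charge: int
    neutral_loss_formula: ElementalFormula
    reagent_fragment_formula: ElementalFormula
    counterion_formula: ElementalFormula

    def __post_init__(self) -> None:
        if self.dication_charge != 2:
            raise ValueError("only doubly charged pairing reagents are modeled")

    @property
    def dication_mass(self) -> float:
        """Mass of the intact dication: monoisotopic − 2 electrons (Da)."""
        return monoisotopic_mass(self.dication_formula) - 2 * ELECTRON_MASS

    @property
    def dication_mz(self) -> float:
        return self.dication_mass / 2

    @property
    def ion_pair_mz(self) -> float:
        """m/z of the +1 ion pair with one counterion (e.g. [R+F]+)."""
        return ion_mz(self.dication_formula + self.counterion_formula, +1)

    @property
    def reagent_fragment_mz(self) -> float:
        return ion_mz(self.reagent_fragment_formula, +1)


def _read_packaged_tsv(name: str, path=None) -> List[List[str]]:
    if path is None:
        text = resources.files("dicationmsi.data").joinpath(name).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def load_reagent(name: str = "C5(bpyr)2", path=None) -> ReagentDefinition:
    """Load a reagent definition from the packaged table (or ``path``)."""
    for row in _read_packaged_tsv("reagents.tsv", path):
        if row[0] == name:
            return ReagentDefinition(
                name=row[0],
                dication_formula=parse_formula(row[1]),
                dication_charge=int(row[2]),
                neutral_loss_formula=parse_formula(row[3]),
                reagent_fragment_formula=parse_formula(row[4]),
                counterion_formula=parse_formula(row[5]),
            )
    raise KeyError(f"reagent {name!r} not found")


@dataclass(frozen=True)
class HeadgroupRule:
    """Per-lipid-class diagnostic fragment rule.

    ``headgroup_neutral`` is the neutral (protonated) headgroup whose anion
    pairs with the reagent; ``None`` means the class is known but has no
    headgroup fragment (FA, PC, DG, TG). ``secondary_neutral_loss`` is an
    additional loss from the headgroup fragment (C2H5N for PE).
    """

    lipid_class: str
    headgroup_neutral: Optional[ElementalFormula] = None
    secondary_neutral_loss: Optional[ElementalFormula] = None


def load_headgroup_rules(path=None) -> Dict[str, HeadgroupRule]:
    rules: Dict[str, HeadgroupRule] = {}
    for row in _read_packaged_tsv("headgroup_rules.tsv", path):
        cls, hg, sec = row[0], row[1], row[2]
        rules[cls] = HeadgroupRule(
            lipid_class=cls,
            headgroup_neutral=None if hg == "-" else parse_formula(hg),
            secondary_neutral_loss=None if sec == "-" else parse_formula(sec),
        )
    return rules


def dication_shift(reagent: Optional[ReagentDefinition] = None) -> float:
    """The constant m/z shift between [M−H]− and [M−H+R]+ (Da)."""
    reagent = reagent or load_reagent()
    return reagent.dication_mass


def anion_mz(metabolite) -> float:
    """m/z of the deprotonated metabolite [M−H]− (= neutral mass − proton)."""
    f = metabolite if isinstance(metabolite, ElementalFormula) else parse_formula(metabolite)
    if f.get("H", 0) < 1:
        raise FormulaError(f"{f} has no abstractable proton")
    return monoisotopic_mass(f) - PROTON_MASS


def adduct_mz(metabolite, reagent: Optional[ReagentDefinition] = None) -> float:
    """m/z of the +1 pairing adduct [M−H+R]+ of a metabolite."""
    return anion_mz(metabolite) + dication_shift(reagent)


def strip_shift(observed_mz: float, reagent: Optional[ReagentDefinition] = None) -> float:
    """Invert :func:`adduct_mz`: candidate [M−H]− m/z of an observed adduct."""
    shift = dication_shift(reagent)
    if observed_mz <= shift:
        raise ValueError(
            f"observed m/z {observed_mz} is not above the reagent shift {shift:.4f}"
        )
    return observed_mz - shift


@dataclass(frozen=True)
class FragmentPrediction:
    label: str
    mz: float
    rule: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


def predict_fragments(
    metabolite,
    lipid_class: str,
    reagent: Optional[ReagentDefinition] = None,
    rules: Optional[Dict[str, HeadgroupRule]] = None,
) -> List[FragmentPrediction]:
    """Predict diagnostic MS/MS fragments of a dication adduct.

    Always emits the generic arm loss [M−H+R−C8H17N]+ and the reagent
    fragment ion; for classes with a headgroup rule additionally the
    headgroup fragment [headgroup+R−C8H17N]+ and, when a secondary neutral
    loss is defined, the secondary fragment. A class absent from the rule
    table gets only the generic fragments, flagged in ``rule``. Output
    order and content are deterministic.
    """
    reagent = reagent or load_reagent()
    rules = rules if rules is not None else load_headgroup_rules()
    loss = monoisotopic_mass(reagent.neutral_loss_formula)
    rname = reagent.name
    lname = str(reagent.neutral_loss_formula)

    known = lipid_class in rules
    flag = "" if known else " (class unknown)"
    preds = [
        FragmentPrediction(
            label=f"[M-H+{rname}-{lname}]+",
            mz=adduct_mz(metabolite, reagent) - loss,
            rule="generic neutral loss" + flag,
        ),
        FragmentPrediction(
            label=f"[{rname}-{lname}-H]+",
            mz=reagent.reagent_fragment_mz,
            rule="reagent fragment" + flag,
        ),
    ]
    if known:
        rule = rules[lipid_class]
        if rule.headgroup_neutral is not None:
            hg_mz = anion_mz(rule.headgroup_neutral) + dication_shift(reagent) - loss
            hgname = str(rule.headgroup_neutral - parse_formula("H"))
            preds.append(
                FragmentPrediction(
                    label=f"[{hgname}+{rname}-{lname}]+",
                    mz=hg_mz,
                    rule=f"headgroup ({lipid_class})",
                )
            )
            if rule.secondary_neutral_loss is not None:
                sec = monoisotopic_mass(rule.secondary_neutral_loss)
                preds.append(
                    FragmentPrediction(
                        label=f"[{hgname}+{rname}-{lname}-{rule.secondary_neutral_loss}]+",
                        mz=hg_mz - sec,
                        rule=f"headgroup secondary loss ({lipid_class})",
                    )
                )
    return preds


def fragments_to_frame(predictions: Sequence[FragmentPrediction]) -> pd.DataFrame:
    """Fragment predictions as a table (label, m/z, rule)."""
    return pd.DataFrame(
        [(p.label, p.mz, p.rule) for p in predictions],
        columns=["label", "mz", "rule"],
    )


@dataclass
class MsmsValidation:
    """Per-fragment match report plus an overall confidence tier.

    Tier ``high``: reagent fragment and at least one class-specific
    (headgroup) fragment found; ``medium``: the generic arm-loss fragment
    found but no class-specific evidence; ``low``: otherwise. A missing
    prediction (e.g. a low-abundance precursor-loss peak) is reported, not
    fatal.
    """

    fragments: List[dict] = field(default_factory=list)
    tier: str = "low"

    @property
    def found(self) -> List[str]:
        return [f["label"] for f in self.fragments if f["found"]]

    @property
    def missing(self) -> List[str]:
        return [f["label"] for f in self.fragments if not f["found"]]


def match_msms(
    predicted: Sequence[FragmentPrediction],
    observed: Sequence[Tuple[float, float]],
    tol_da: float = 0.01,
) -> MsmsValidation:
    """Match predicted fragments against an observed MS/MS peak list.

    Each prediction is paired with the nearest observed peak within
    ``tol_da`` (default 0.01 Da, consistent with a 1.0–1.5 Da isolation
    window and high-resolution product-ion detection). An empty spectrum
    yields all-missing, tier ``low``.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    peaks = sorted((float(mz), float(ab)) for mz, ab in observed)
    report = MsmsValidation()
    reagent_found = False
    class_found = False
    generic_found = False
    for pred in predicted:
        best = None
        for mz, ab in peaks:
            err = mz - pred.mz
            if abs(err) <= tol_da and (best is None or abs(err) < abs(best[1])):
                best = (mz, err, ab)
        entry = {
            "label": pred.label,
            "predicted_mz": pred.mz,
            "rule": pred.rule,
            "found": best is not None,
            "observed_mz": best[0] if best else None,
            "error_da": best[1] if best else None,
        }
        report.fragments.append(entry)
        if best is not None:
            if pred.rule.startswith("reagent fragment"):
                reagent_found = True
            elif pred.rule.startswith("headgroup"):
                class_found = True
            elif pred.rule.startswith("generic neutral loss"):
                generic_found = True
    if reagent_found and class_found:
        report.tier = "high"
    elif generic_found:
        report.tier = "medium"
    else:
        report.tier = "low"
    return report
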