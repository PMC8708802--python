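"""imzML-backed pixel-grid processing and mass-shift adduct annotation.

The analysis path mirrors standard MSI peak-finding practice:

1. read a centroided imzML pixel grid (:func:`read_imzml`);
2. cluster peaks across pixels at ppm tolerance into consensus peaks
   (:func:`cluster_peaks`);
3. keep tissue-specific peaks — mean on-tissue abundance at least
   ``ratio_min`` (default 1.5×) the off-tissue mean (:func:`find_tissue_peaks`);
4. annotate each peak against an offline formula library at ±2.5 ppm mass
   measurement accuracy, treating an adducted-positive run's peaks as
   either protonated species or pairing-reagent adducts whose m/z minus
   the dication mass matches a deprotonated metabolite
   (:func:`annotate_dataset`);
5. summarize cross-polarity overlap and the coverage gain from adduct
   formation (:func:`cross_mode_overlap`, :func:`coverage_report`), and
   render per-m/z ion images (:func:`ion_image`).

Annotation is candidate listing at a stated mass tolerance, optionally
supported by isotope spectral accuracy and a paired plain-positive run; no
multiple-testing control is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .adducts import ReagentDefinition, load_reagent, strip_shift
from .chem import ELECTRON_MASS, PROTON_MASS, parse_formula, spectral_accuracy_score

__all__ = [
    "POLARITIES",
    "LABEL_DEPROTONATED",
    "LABEL_PROTONATED",
    "MsiDataset",
    "RoiMask",
    "ConsensusPeak",
    "AnnotationRecord",
    "OverlapCounts",
    "CoverageReport",
    "adduct_label",
    "read_imzml",
    "write_imzml",
    "cluster_peaks",
    "find_tissue_peaks",
    "load_library",
    "library_search",
    "annotate_dataset",
    "annotations_to_frame",
    "cross_mode_overlap",
    "coverage_report",
    "ion_image",
]

POLARITIES = ("negative", "positive", "adducted_positive")

LABEL_DEPROTONATED = "[M-H]-"
LABEL_PROTONATED = "[M+H]+"

#: Nominal M..M+1 spacing (13C−12C), used for isotope flagging.
C13_SPACING = 1.003355


def adduct_label(reagent: Optional[ReagentDefinition] = None) -> str:
    reagent = reagent or load_reagent()
    return f"[M-H+{reagent.name}]+"


# ---------------------------------------------------------------------------
# Dataset container and imzML I/O
# ---------------------------------------------------------------------------


@dataclass
class MsiDataset:
    """A rectangular grid of centroided peak lists.

    ``spectra`` maps 0-based ``(x, y)`` (x the fastest axis, row-major) to a
    pair of equal-length float64 arrays ``(mz, intensity)``. Pixels may be
    empty (zero-length arrays) but every coordinate inside ``shape`` is a
    real pixel.
    """

    shape: Tuple[int, int]
    spectra: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]]
    polarity: str
    mz_window: Tuple[float, float]
    pixel_pitch_um: float = 150.0

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        nx, ny = self.shape
        lo, hi = self.mz_window
        norm: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}
        for (x, y), (mz, inten) in self.spectra.items():
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError(f"pixel ({x},{y}) outside grid {self.shape}")
            mz = np.asarray(mz, dtype=np.float64)
            inten = np.asarray(inten, dtype=np.float64)
            if mz.shape != inten.shape:
                raise ValueError(f"ragged spectrum at ({x},{y})")
            if mz.size and ((mz < lo).any() or (mz > hi).any()):
                raise ValueError(f"peak outside m/z window at ({x},{y})")
            if inten.size and (inten < 0).any():
                raise ValueError(f"negative abundance at ({x},{y})")
            norm[(int(x), int(y))] = (mz, inten)
        self.spectra = norm

    def cells(self) -> Iterable[Tuple[int, int]]:
        nx, ny = self.shape
        for y in range(ny):
            for x in range(nx):
                yield (x, y)

    def spectrum(self, x: int, y: int) -> Tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.float64)
        return self.spectra.get((x, y), (empty, empty))

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]


@dataclass(frozen=True)
class RoiMask:
    """Disjoint on-tissue / off-tissue pixel sets."""

    on_tissue: frozenset
    off_tissue: frozenset

    def __post_init__(self) -> None:
        if self.on_tissue & self.off_tissue:
            raise ValueError("on- and off-tissue masks overlap")

    @classmethod
    def from_rectangles(
        cls,
        on_origin: Tuple[int, int],
        on_shape: Tuple[int, int],
        off_origin: Tuple[int, int],
        off_shape: Tuple[int, int],
    ) -> "RoiMask":
        def rect(origin, shape):
            ox, oy = origin
            nx, ny = shape
            return frozenset((ox + x, oy + y) for x in range(nx) for y in range(ny))

        return cls(on_tissue=rect(on_origin, on_shape), off_tissue=rect(off_origin, off_shape))


def _sidecar_path(path) -> Path:
    path = Path(path)
    stem = path.name
    for ext in (".imzML", ".imzml"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    return path.with_name(stem + ".meta.json")


def write_imzml(dataset: MsiDataset, path) -> None:
    """Write a processed-mode imzML/ibd pair plus a JSON metadata sidecar.

    m/z and intensities are stored as float64, so the round trip is exact.
    The imzML standard cannot hold zero-length spectra, so empty pixels are
    listed in the sidecar and restored on read.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    scan_polarity = "negative" if dataset.polarity == "negative" else "positive"
    empty_pixels: List[List[int]] = []
    with ImzMLWriter(
        str(path),
        polarity=scan_polarity,
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        mode="processed",
    ) as writer:
        for (x, y) in dataset.cells():
            mz, inten = dataset.spectrum(x, y)
            if mz.size == 0:
                empty_pixels.append([x, y])
                continue
            writer.addSpectrum(mz, inten, (x + 1, y + 1, 1))
    meta = {
        "polarity": dataset.polarity,
        "mz_window": list(dataset.mz_window),
        "pixel_pitch_um": dataset.pixel_pitch_um,
        "shape": list(dataset.shape),
        "empty_pixels": empty_pixels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_imzml(path) -> MsiDataset:
    """Read a (processed or continuous) imzML file into an :class:`MsiDataset`.

    Coordinates are converted to 0-based. Grid gaps — coordinates missing
    from both the file and the sidecar's declared empty pixels — are filled
    as empty pixels with a warning.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    spectra: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}
    for i, coord in enumerate(parser.coordinates):
        x, y = int(coord[0]) - 1, int(coord[1]) - 1
        mz, inten = parser.getspectrum(i)
        spectra[(x, y)] = (
            np.asarray(mz, dtype=np.float64),
            np.asarray(inten, dtype=np.float64),
        )

    sidecar = _sidecar_path(path)
    declared_empty: set = set()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        polarity = meta["polarity"]
        mz_window = tuple(meta["mz_window"])
        pitch = float(meta["pixel_pitch_um"])
        declared_empty = {tuple(p) for p in meta.get("empty_pixels", [])}
    else:
        nx = max((x for x, _ in spectra), default=-1) + 1
        ny = max((y for _, y in spectra), default=-1) + 1
        shape = (nx, ny)
        polarity = "positive"
        lo = min((mz.min() for mz, _ in spectra.values() if mz.size), default=0.0)
        hi = max((mz.max() for mz, _ in spectra.values() if mz.size), default=1.0)
        mz_window = (float(lo), float(hi))
        pitch = 150.0

    empty = np.empty(0, dtype=np.float64)
    nx, ny = shape
    for y in range(ny):
        for x in range(nx):
            if (x, y) not in spectra:
                if (x, y) not in declared_empty:
                    warnings.warn(f"coordinate gap at ({x},{y}); filled as empty pixel")
                spectra[(x, y)] = (empty, empty)
    return MsiDataset(
        shape=shape,
        spectra=spectra,
        polarity=polarity,
        mz_window=mz_window,
        pixel_pitch_um=pitch,
    )


# ---------------------------------------------------------------------------
# Peak clustering and tissue-specific filtering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusPeak:
    """A cross-pixel peak cluster.

    ``mean_on`` / ``mean_off`` are averages over *all* mask pixels (pixels
    lacking the peak contribute zero), so sporadic noise is penalized;
    ``pixel_frequency`` is the fraction of on-tissue (or clustered-mask)
    pixels containing the peak.
    """

    mz: float
    mean_on: float
    mean_off: float
    pixel_frequency: float
    n_members: int = 0


class _Cluster:
    __slots__ = ("wsum_mz", "wsum", "members", "cells")

    def __init__(self) -> None:
        self.wsum_mz = 0.0
        self.wsum = 0.0
        self.members: List[Tuple[Tuple[int, int], float, float]] = []
        self.cells: set = set()

    def add(self, cell, mz, inten) -> None:
        w = inten if inten > 0 else 1e-30
        self.wsum_mz += w * mz
        self.wsum += w
        self.members.append((cell, mz, inten))
        self.cells.add(cell)

    @property
    def mean(self) -> float:
        return self.wsum_mz / self.wsum


def _cluster_items(
    items: List[Tuple[Tuple[int, int], float, float]], tol_ppm: float
) -> List[_Cluster]:
    """Greedy abundance-ranked clustering at ppm tolerance.

    Peaks are visited in order of decreasing abundance; each joins the
    first cluster — clusters ranked by the abundance of their seed peak,
    i.e. creation order — whose running abundance-weighted mean is within
    ``tol_ppm`` and that has no peak from the same pixel yet, else it
    seeds a new cluster. Ranking by cluster prominence rather than by
    proximity keeps rare jitter outliers from seeding satellites that
    drain the main cluster. Deterministic and pixel-order invariant (up
    to exact abundance ties, broken by m/z).
    """
    items = sorted(items, key=lambda t: (-t[2], t[1], t[0]))
    clusters: List[_Cluster] = []
    means = np.empty(0, dtype=np.float64)
    for cell, mz, inten in items:
        chosen = None
        if len(clusters):
            diff_ppm = np.abs(means[: len(clusters)] - mz) / mz * 1e6
            for idx in np.nonzero(diff_ppm <= tol_ppm)[0]:
                if cell not in clusters[idx].cells:
                    chosen = int(idx)
                    break
        if chosen is None:
            clusters.append(_Cluster())
            chosen = len(clusters) - 1
            if len(clusters) > means.size:
                means = np.concatenate([means, np.empty(max(64, means.size), dtype=np.float64)])
        clusters[chosen].add(cell, mz, inten)
        means[chosen] = clusters[chosen].mean
    return clusters


def _gather(dataset: MsiDataset, cells) -> List[Tuple[Tuple[int, int], float, float]]:
    items = []
    for cell in cells:
        mz, inten = dataset.spectrum(*cell)
        for j in range(mz.size):
            items.append((cell, float(mz[j]), float(inten[j])))
    return items


def _consensus(
    clusters: List[_Cluster], on_cells: frozenset, off_cells: frozenset
) -> List[ConsensusPeak]:
    n_on = max(len(on_cells), 1)
    n_off = len(off_cells)
    out = []
    for cl in clusters:
        sum_on = sum(i for c, _, i in cl.members if c in on_cells)
        sum_off = sum(i for c, _, i in cl.members if c in off_cells)
        freq = len({c for c, _, _ in cl.members if c in on_cells}) / n_on
        out.append(
            ConsensusPeak(
                mz=cl.mean,
                mean_on=sum_on / n_on,
                mean_off=sum_off / n_off if n_off else 0.0,
                pixel_frequency=freq,
                n_members=len(cl.members),
            )
        )
    out.sort(key=lambda p: p.mz)
    return out


def cluster_peaks(
    dataset: MsiDataset, mask_cells, tol_ppm: float = 2.5
) -> List[ConsensusPeak]:
    """Cluster peaks across the given pixels into consensus peaks."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mask_cells = frozenset(mask_cells)
    if not mask_cells:
        raise ValueError("empty pixel mask")
    clusters = _cluster_items(_gather(dataset, mask_cells), tol_ppm)
    return _consensus(clusters, mask_cells, frozenset())


def find_tissue_peaks(
    dataset: MsiDataset,
    mask: RoiMask,
    ratio_min: float = 1.5,
    tol_ppm: float = 2.5,
    min_frequency: float = 0.05,
) -> List[ConsensusPeak]:
    """Tissue-specific consensus peaks: on/off abundance ratio ≥ ``ratio_min``.

    Clusters are built over the union of on- and off-tissue pixels. A
    cluster with zero off-tissue mean is ratioed against the smallest
    positive off-tissue mean among all clusters (machine-tiny fallback), so
    genuinely tissue-specific peaks survive without infinite ratios.
    ``min_frequency`` additionally requires a peak in at least that
    fraction of on-tissue pixels: mass-jitter outliers of an abundant ion
    form sporadic low-frequency clusters which, when their few members all
    happen to fall on tissue, would otherwise pass the ratio filter.
    """
    if ratio_min <= 0:
        raise ValueError("ratio_min must be positive")
    if not mask.on_tissue or not mask.off_tissue:
        raise ValueError("both on- and off-tissue masks must be non-empty")
    clusters = _cluster_items(
        _gather(dataset, mask.on_tissue | mask.off_tissue), tol_ppm
    )
    peaks = _consensus(clusters, mask.on_tissue, mask.off_tissue)
    positive_offs = [p.mean_off for p in peaks if p.mean_off > 0]
    eps = min(positive_offs) if positive_offs else np.finfo(np.float64).tiny
    return [
        p
        for p in peaks
        if p.pixel_frequency >= min_frequency
        and p.mean_on >= ratio_min * max(p.mean_off, eps)
    ]


# ---------------------------------------------------------------------------
# Library search and annotation
# ---------------------------------------------------------------------------


def load_library(path=None) -> pd.DataFrame:
    """Load the metabolite formula library (name, formula, class, polarity)."""
    if path is None:
        with resources.files("dicationmsi.data").joinpath(
            "metabolite_library.tsv"
        ).open("rb") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", header=None)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = ["name", "formula", "lipid_class", "expected_polarity"]
    return df


@dataclass
class AnnotationRecord:
    """One observed peak → one candidate metabolite under one ion label."""

    observed_mz: float
    name: Optional[str] = None
    formula: Optional[str] = None
    lipid_class: Optional[str] = None
    ion_label: Optional[str] = None
    mma_ppm: Optional[float] = None
    spectral_accuracy: str = "untested"
    cross_polarity_confirmed: bool = False
    msms_tier: Optional[str] = None
    evidence: str = ""
    mean_on: float = 0.0
    mean_off: float = 0.0
    pixel_frequency: float = 0.0

    @property
    def annotated(self) -> bool:
        return self.name is not None

    @property
    def identity(self) -> Optional[Tuple[str, str]]:
        return (self.name, self.formula) if self.annotated else None


def _theoretical_mz(formula_str: str, ion_label: str, reagent: ReagentDefinition) -> float:
    f = parse_formula(formula_str)
    mass = chem.monoisotopic_mass(f)
    if ion_label == LABEL_DEPROTONATED:
        return mass - PROTON_MASS
    if ion_label == LABEL_PROTONATED:
        return mass + PROTON_MASS
    if ion_label == adduct_label(reagent):
        return mass - PROTON_MASS + reagent.dication_mass
    raise ValueError(f"unsupported ion label {ion_label!r}")


def library_search(
    mz: float,
    library: pd.DataFrame,
    ion_label: str,
    tol_ppm: float = 2.5,
    reagent: Optional[ReagentDefinition] = None,
) -> List[AnnotationRecord]:
    """All library candidates for an observed m/z under one ion label.

    For the pairing-adduct label the query is ``strip_shift(mz)`` compared
    against library [M−H]− masses, mirroring mass-shift subtraction prior
    to database search. The ppm error is evaluated relative to the
    theoretical mass. Candidates are sorted by |mma_ppm|; isomers tie.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    reagent = reagent or load_reagent()
    is_adduct = ion_label == adduct_label(reagent)
    query = strip_shift(mz, reagent) if is_adduct else mz
    records: List[AnnotationRecord] = []
    for row in library.itertuples(index=False):
        base_label = LABEL_DEPROTONATED if is_adduct else ion_label
        theory = _theoretical_mz(row.formula, base_label, reagent)
        mma = (query - theory) / theory * 1e6
        if abs(mma) <= tol_ppm:
            records.append(
                AnnotationRecord(
                    observed_mz=mz,
                    name=row.name,
                    formula=row.formula,
                    lipid_class=row.lipid_class,
                    ion_label=ion_label,
                    mma_ppm=mma,
                )
            )
    records.sort(key=lambda r: (abs(r.mma_ppm), r.name))
    return records


def _flag_isotopes(peaks: Sequence[ConsensusPeak], tol_ppm: float) -> List[bool]:
    """Charge-1 deisotoping: True where a peak is an M+1/M+2 companion.

    A peak is flagged when a more abundant peak sits one or two nominal
    13C spacings below it within tolerance.
    """
    flags = [False] * len(peaks)
    mzs = np.array([p.mz for p in peaks])
    mean_on = np.array([p.mean_on for p in peaks])
    for i, p in enumerate(peaks):
        for k in (1, 2):
            target = p.mz - k * C13_SPACING
            diff_ppm = np.abs(mzs - target) / target * 1e6
            cand = np.where((diff_ppm <= tol_ppm) & (mean_on > p.mean_on))[0]
            if cand.size:
                flags[i] = True
                break
    return flags


def _present_near(mz: float, other_mzs: np.ndarray, tol_ppm: float) -> bool:
    if other_mzs.size == 0:
        return False
    return bool((np.abs(other_mzs - mz) / mz * 1e6 <= tol_ppm).any())


def annotate_dataset(
    peaks: Sequence[ConsensusPeak],
    polarity: str,
    library: pd.DataFrame,
    reagent: Optional[ReagentDefinition] = None,
    *,
    paired_positive: Optional[Sequence] = None,
    paired_negative: Optional[Sequence] = None,
    tol_ppm: float = 2.5,
    deisotope: bool = True,
    sa_threshold: float = 0.20,
) -> List[AnnotationRecord]:
    """Annotate tissue-specific consensus peaks against the formula library.

    In ``adducted_positive`` polarity each peak is searched under both the
    protonated label and the pairing-adduct label. When ``paired_positive``
    (consensus peaks, or plain m/z values, of the matching plain-positive
    run) is given, peaks also present there are excluded from adduct
    assignment — adduct candidacy requires being observed *only* in the
    adducted run. Without a paired run, adduct assignment falls back to
    m/z-only with ``evidence="mz_only"``.

    Spectral accuracy of each candidate is evaluated from the cluster mean
    on-tissue abundances whenever the M+1 cluster is detectable; records
    failing the M+1 deviation threshold are retained and flagged. Peaks
    explained as isotope companions of a stronger peak are carried through
    unannotated. ``paired_negative`` marks adduct candidates whose stripped
    mass is also seen in a paired negative-mode run.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    reagent = reagent or load_reagent()
    shift = reagent.dication_mass

    def to_mzs(seq) -> np.ndarray:
        if seq is None:
            return np.empty(0)
        vals = [p.mz if isinstance(p, ConsensusPeak) else float(p) for p in seq]
        return np.asarray(sorted(vals), dtype=np.float64)

    paired_pos_mzs = to_mzs(paired_positive)
    paired_neg_mzs = to_mzs(paired_negative)

    if polarity == "negative":
        labels = [LABEL_DEPROTONATED]
    elif polarity == "positive":
        labels = [LABEL_PROTONATED]
    else:
        labels = [LABEL_PROTONATED, adduct_label(reagent)]

    iso_flags = _flag_isotopes(peaks, tol_ppm) if deisotope else [False] * len(peaks)
    envelope = [(p.mz, p.mean_on) for p in peaks]

    records: List[AnnotationRecord] = []
    for peak, is_iso in zip(peaks, iso_flags):
        base = dict(
            observed_mz=peak.mz,
            mean_on=peak.mean_on,
            mean_off=peak.mean_off,
            pixel_frequency=peak.pixel_frequency,
        )
        if is_iso:
            records.append(AnnotationRecord(evidence="isotope peak", **base))
            continue
        candidates: List[AnnotationRecord] = []
        for label in labels:
            is_adduct = label == adduct_label(reagent)
            if is_adduct:
                if peak.mz <= shift:
                    continue
                if paired_positive is not None and _present_near(
                    peak.mz, paired_pos_mzs, tol_ppm
                ):
                    continue  # seen unmodified in plain positive: not an adduct
            found = library_search(peak.mz, library, label, tol_ppm, reagent)
            for rec in found:
                for key, val in base.items():
                    setattr(rec, key, val)
                if is_adduct:
                    rec.evidence = "paired" if paired_positive is not None else "mz_only"
                    rec.cross_polarity_confirmed = _present_near(
                        peak.mz - shift, paired_neg_mzs, tol_ppm
                    )
                f = parse_formula(rec.formula)
                if label == LABEL_PROTONATED:
                    ion_comp, charge = f + parse_formula("H"), +1
                elif label == LABEL_DEPROTONATED:
                    ion_comp, charge = f - parse_formula("H"), -1
                else:
                    ion_comp = f - parse_formula("H") + reagent.dication_formula
                    charge = +1
                sa = spectral_accuracy_score(
                    envelope, ion_comp, tol_ppm=tol_ppm, charge=charge,
                    m1_threshold=sa_threshold,
                )
                if sa.passed is None:
                    rec.spectral_accuracy = "untested"
                else:
                    rec.spectral_accuracy = "pass" if sa.passed else "fail"
                candidates.append(rec)
        if candidates:
            records.extend(candidates)
        else:
            records.append(AnnotationRecord(**base))
    return records


_FRAME_COLUMNS = [
    "observed_mz",
    "name",
    "formula",
    "lipid_class",
    "ion_label",
    "mma_ppm",
    "spectral_accuracy",
    "cross_polarity_confirmed",
    "msms_tier",
    "evidence",
    "mean_on",
    "mean_off",
    "pixel_frequency",
]


def annotations_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Annotation records as a table with a fixed, documented column order."""
    return pd.DataFrame(
        [{col: getattr(r, col) for col in _FRAME_COLUMNS} for r in records],
        columns=_FRAME_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Cross-mode comparison and reporting
# ---------------------------------------------------------------------------


class OverlapCounts(NamedTuple):
    a_only: int
    shared: int
    b_only: int


def _identities(records: Sequence[AnnotationRecord], ion_label=None) -> set:
    return {
        r.identity
        for r in records
        if r.annotated and (ion_label is None or r.ion_label == ion_label)
    }


def cross_mode_overlap(
    annotations_a: Sequence[AnnotationRecord],
    annotations_b: Sequence[AnnotationRecord],
) -> OverlapCounts:
    """Set algebra on annotated metabolite identities (name + formula)."""
    a = _identities(annotations_a)
    b = _identities(annotations_b)
    return OverlapCounts(len(a - b), len(a & b), len(b - a))


@dataclass
class CoverageReport:
    """Coverage gain from adduct formation, with its definition printed.

    ``percent_increase = round(100 × n_adduct_new / n_positive)`` — newly
    adduct-annotated metabolites relative to the plain positive-mode count.
    """

    n_positive: int
    n_retained: int
    n_adduct_new: int
    definition: str = (
        "percent_increase = 100 * n_adduct_new / n_positive, rounded to nearest integer"
    )

    def __post_init__(self) -> None:
        if self.n_positive <= 0:
            raise ValueError("n_positive must be positive")

    @property
    def percent_increase(self) -> int:
        return int(round(100.0 * self.n_adduct_new / self.n_positive))

    def __str__(self) -> str:
        return (
            "Coverage report\n"
            f"  positive-mode metabolites           : {self.n_positive}\n"
            f"  retained in adducted-positive mode  : {self.n_retained}\n"
            f"  new pairing-adduct metabolites      : {self.n_adduct_new}\n"
            f"  coverage increase                   : {self.percent_increase}%\n"
            f"  definition: {self.definition}"
        )


def coverage_report(
    positive_annotations: Sequence[AnnotationRecord],
    adducted_annotations: Sequence[AnnotationRecord],
    reagent: Optional[ReagentDefinition] = None,
) -> CoverageReport:
    """Coverage gain of an adducted-positive run over its plain-positive pair."""
    reagent = reagent or load_reagent()
    positive_ids = _identities(positive_annotations, LABEL_PROTONATED)
    retained = positive_ids & _identities(adducted_annotations, LABEL_PROTONATED)
    new = _identities(adducted_annotations, adduct_label(reagent)) - positive_ids
    return CoverageReport(
        n_positive=len(positive_ids),
        n_retained=len(retained),
        n_adduct_new=len(new),
    )


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------


def ion_image(
    dataset: MsiDataset, target_mz: float, tol_ppm: float = 2.5
) -> np.ndarray:
    """Per-pixel summed abundance within ``tol_ppm`` of ``target_mz``.

    Returns a ``(ny, nx)`` array, row-major with pixel (0,0) top-left.
    A target outside the dataset's m/z window yields an all-zero image
    with a warning.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    nx, ny = dataset.shape
    img = np.zeros((ny, nx), dtype=np.float64)
    lo, hi = dataset.mz_window
    if not (lo <= target_mz <= hi):
        warnings.warn(
            f"target m/z {target_mz} outside window [{lo}, {hi}]; image is all zeros"
        )
        return img
    half = target_mz * tol_ppm * 1e-6
    for (x, y), (mz, inten) in dataset.spectra.items():
        if mz.size == 0:
            continue
        sel = np.abs(mz - target_mz) <= half
        if sel.any():
            img[y, x] = inten[sel].sum()
    return img
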