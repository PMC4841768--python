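"""MS1-level quantitation of PTM proteoforms from extracted ion chromatograms.

A peptide can exist as several proteoforms (modification states) that differ
by a fixed mass shift (O-GlcNAc/HexNAc: +203.079373 Da; phosphate:
+79.966331 Da) and, for positional isomers, only by retention time.  The
relative abundance of each form is estimated label-free from MS1 survey
scans: an extracted ion chromatogram (XIC) is built for each form's
theoretical m/z at a ppm tolerance, its area is integrated over a
caller-supplied retention-time window, and the fraction of total signal
carried by each form is the PTM stoichiometry.

Integration is a baseline-subtracted trapezoid (baseline = window minimum):
a documented, reproducible stand-in for vendor chromatographic peak-area
algorithms, which agree with it to within noise for well-formed peaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "MOD_MASSES",
    "RESIDUE_MASSES",
    "ModifiedPeptide",
    "Scan",
    "MS1Run",
    "XICTrace",
    "compute_isoform_mz",
    "extract_xic",
    "integrate_area",
    "stoichiometry",
    "quantify_isoforms",
    "mean_stoichiometry",
]

PROTON_MASS = 1.007276466
WATER_MASS = 18.010565

#: Monoisotopic mass deltas of the supported modifications (Da).
MOD_MASSES = {"HexNAc": 203.079373, "Phospho": 79.966331}

#: Residues each modification kind may occupy.
_MOD_TARGETS = {"HexNAc": frozenset("ST"), "Phospho": frozenset("STY")}

#: Monoisotopic residue masses (Da), single-letter amino acid codes.
RESIDUE_MASSES: dict[str, float] = {
    aa: m for aa, m in _ptmass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence plus site-localised modifications and a charge.

    Parameters
    ----------
    sequence
        Uppercase one-letter amino acid string.
    modifications
        Iterable of ``(site, kind)`` with 0-based site index and kind in
        ``{"HexNAc", "Phospho"}``.  Sites must be unique and chemically
        plausible (HexNAc on S/T; Phospho on S/T/Y).
    charge
        Positive precursor charge.
    label
        Free-text isoform name used in stoichiometry tables.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 2
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "modifications", tuple((int(i), str(k)) for i, k in self.modifications)
        )
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue letter {ch!r} in {self.sequence!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        seen: set[int] = set()
        for site, kind in self.modifications:
            if kind not in MOD_MASSES:
                raise ValueError(f"unknown modification kind {kind!r}")
            if not 0 <= site < len(self.sequence):
                raise ValueError(
                    f"modification site {site} outside sequence of length {len(self.sequence)}"
                )
            if site in seen:
                raise ValueError(f"two modifications share site index {site}")
            seen.add(site)
            residue = self.sequence[site]
            if residue not in _MOD_TARGETS[kind]:
                raise ValueError(
                    f"{kind} at site {site} requires one of "
                    f"{sorted(_MOD_TARGETS[kind])}, found {residue!r}"
                )

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass: residues + water + modification deltas."""
        mass = sum(RESIDUE_MASSES[aa] for aa in self.sequence) + WATER_MASS
        mass += sum(MOD_MASSES[kind] for _, kind in self.modifications)
        return mass

    @property
    def mz(self) -> float:
        return compute_isoform_mz(self)


def compute_isoform_mz(peptide: ModifiedPeptide) -> float:
    """Theoretical m/z (Th) of a modified peptide at its charge state."""
    return (peptide.neutral_mass + peptide.charge * PROTON_MASS) / peptide.charge


@dataclass
class Scan:
    """One MS1 survey scan: retention time (minutes) and centroids."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative centroid intensity")


@dataclass
class MS1Run:
    """An ordered list of MS1 scans with strictly increasing retention times."""

    scans: list[Scan] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rt_bounds(self) -> tuple[float, float]:
        if not self.scans:
            return (0.0, 0.0)
        return (self.scans[0].rt, self.scans[-1].rt)


@dataclass
class XICTrace:
    """Extracted ion chromatogram: per-scan summed intensity near a target m/z."""

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    def __len__(self) -> int:
        return len(self.rt)


def extract_xic(
    run: MS1Run,
    target_mz: float,
    tolerance_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XICTrace:
    """Build the XIC of ``target_mz`` at ``tolerance_ppm`` over ``rt_window``.

    Each scan inside the window contributes one point whose intensity is the
    sum of centroid intensities with relative mass error at most
    ``tolerance_ppm``; scans with no matching centroid contribute 0.  An
    empty run yields an empty trace.
    """
    if tolerance_ppm <= 0:
        raise ValueError(f"tolerance_ppm must be positive, got {tolerance_ppm}")
    if rt_window is not None:
        lo, hi = rt_window
        if lo > hi:
            raise ValueError(f"inverted rt_window ({lo}, {hi})")
    half_width = target_mz * tolerance_ppm * 1e-6
    rts: list[float] = []
    vals: list[float] = []
    for scan in run.scans:
        if rt_window is not None and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        rts.append(scan.rt)
        if scan.mz.size:
            sel = np.abs(scan.mz - target_mz) <= half_width
            vals.append(float(scan.intensity[sel].sum()))
        else:
            vals.append(0.0)
    return XICTrace(target_mz, tolerance_ppm, np.array(rts), np.array(vals))


def integrate_area(trace: XICTrace) -> float:
    """Baseline-subtracted trapezoidal XIC area (intensity x minutes).

    Baseline is the minimum intensity in the trace window; the integrand is
    clipped below at 0.  Traces with fewer than two points have zero area.
    """
    if len(trace) < 2:
        return 0.0
    baseline = float(trace.intensity.min())
    y = np.clip(trace.intensity - baseline, 0.0, None)
    return float(np.trapezoid(y, trace.rt))


def stoichiometry(
    areas: Mapping[str, float] | Iterable[tuple[str, float]],
    loq_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-isoform fraction of total integrated signal.

    Parameters
    ----------
    areas
        Mapping or sequence of ``(isoform label, integrated area)``; areas
        must be non-negative and at least one positive.
    loq_fraction
        Fractions below this are flagged ``below_loq`` (limit of
        quantitation) but retained in the table and in the normalisation.

    Returns
    -------
    DataFrame with columns ``label, area, fraction, below_loq``; fractions
    sum to 1.
    """
    items = list(areas.items()) if isinstance(areas, Mapping) else list(areas)
    if not items:
        raise ValueError("no isoform areas given")
    labels = [str(k) for k, _ in items]
    vals = np.array([float(v) for _, v in items])
    if np.any(vals < 0):
        raise ValueError("negative isoform area")
    total = vals.sum()
    if total <= 0:
        raise ValueError("all isoform areas are zero: no quantifiable signal")
    frac = vals / total
    return pd.DataFrame(
        {
            "label": labels,
            "area": vals,
            "fraction": frac,
            "below_loq": frac < loq_fraction,
        }
    )


def _isobaric(mz_a: float, mz_b: float, tolerance_ppm: float) -> bool:
    return abs(mz_a - mz_b) <= 2e-6 * tolerance_ppm * max(mz_a, mz_b)


def quantify_isoforms(
    run: MS1Run,
    isoforms: Sequence[ModifiedPeptide],
    tolerance_ppm: float = 10.0,
    rt_windows: Mapping[str, tuple[float, float]] | None = None,
    loq_fraction: float = 0.01,
) -> pd.DataFrame:
    """XIC-extract, integrate and normalise a set of PTM isoforms.

    One XIC is extracted per ``ModifiedPeptide`` (so per charge state) in its
    label's retention-time window; areas are summed across charge states per
    label, then :func:`stoichiometry` is applied.  Positional isomers of
    identical mass must be given disjoint windows — their XICs are otherwise
    indistinguishable — and overlapping windows for such a pair are rejected.
    """
    if not isoforms:
        raise ValueError("no isoforms given")
    rt_windows = dict(rt_windows or {})
    labels: list[str] = []
    for p in isoforms:
        if p.label not in labels:
            labels.append(p.label)
    for lbl in labels:
        if lbl not in rt_windows:
            raise ValueError(f"no rt_window given for isoform {lbl!r}")

    by_label = {lbl: [p for p in isoforms if p.label == lbl] for lbl in labels}
    for la, lb in itertools.combinations(labels, 2):
        wa, wb = rt_windows[la], rt_windows[lb]
        overlap = wa[0] < wb[1] and wb[0] < wa[1]
        if overlap and any(
            _isobaric(pa.mz, pb.mz, tolerance_ppm)
            for pa in by_label[la]
            for pb in by_label[lb]
        ):
            raise ValueError(
                f"isobaric isoforms {la!r} and {lb!r} have overlapping rt_windows; "
                "positional isomers must be separated chromatographically"
            )

    areas = {
        lbl: sum(
            integrate_area(extract_xic(run, p.mz, tolerance_ppm, rt_windows[lbl]))
            for p in peps
        )
        for lbl, peps in by_label.items()
    }
    return stoichiometry(areas, loq_fraction=loq_fraction)


def mean_stoichiometry(tables: Sequence[pd.DataFrame], loq_fraction: float = 0.01) -> pd.DataFrame:
    """Average per-replicate fractions (replicates quantified separately).

    Mirrors reporting a mean percentage over n replicate runs: each
    replicate's fractions are computed first, then averaged and renormalised;
    the LOQ flag is re-derived from the mean fraction.
    """
    if not tables:
        raise ValueError("no replicate tables given")
    merged = pd.concat([t.set_index("label")["fraction"] for t in tables])
    mean = merged.groupby(level=0, sort=False).mean()
    mean = mean / mean.sum()
    return pd.DataFrame(
        {
            "label": mean.index,
            "fraction": mean.values,
            "below_loq": mean.values < loq_fraction,
        }
    ).reset_index(drop=True)
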