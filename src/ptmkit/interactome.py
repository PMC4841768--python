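"""AP-MS interactome scoring from label-free quantitation (LFQ) tables.

Co-immunoprecipitations against a FLAG-tagged bait (wild-type or S248A SOX2)
are compared with an HA-tagged control purification.  Two statistics drive
the calls:

* specificity — per protein of interest (POI), the log2 ratio of mean FLAG
  intensity over mean HA intensity, centred on the global median; POIs at
  least ``sd_threshold`` sample standard deviations above the mean of the
  centred ratios are called bait-specific.  The call is one-sided: depleted
  proteins are not interactors.
* differential interaction — the log2 ratio-of-ratios (S248A/HA over WT/HA,
  in which the HA term cancels), median-centred and z-scored; |z| above
  ``z_threshold`` classifies a POI as preferring one bait form.

Protein intensities may be rolled up from peptide tables, excluding
homologous (shared) peptides and, for the bait itself, peptides overlapping
a modified region so the modification state cannot bias bait quantitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TAG_FLAG_WT",
    "TAG_FLAG_S248A",
    "TAG_HA",
    "IntensityTable",
    "rollup_protein_intensity",
    "specificity_score",
    "specific_interactors",
    "differential_score",
    "targeted_top2",
]

TAG_FLAG_WT = "FLAG_WT"
TAG_FLAG_S248A = "FLAG_S248A"
TAG_HA = "HA_control"

_KNOWN_TAGS = (TAG_FLAG_WT, TAG_FLAG_S248A, TAG_HA)


@dataclass
class IntensityTable:
    """Protein x sample LFQ intensities with bait/replicate metadata.

    ``intensities``: DataFrame indexed by protein id, one column per sample;
    NaN marks a missing (not-detected) value, everything else must be >= 0.
    ``metadata``: DataFrame indexed by sample name with columns ``tag``
    (one of FLAG_WT, FLAG_S248A, HA_control) and ``replicate``.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.intensities.columns if c not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("tag", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad = set(self.metadata["tag"]) - set(_KNOWN_TAGS)
        if bad:
            raise ValueError(f"unknown bait tags {sorted(bad)}; expected {_KNOWN_TAGS}")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative LFQ intensity")

    def samples_with_tag(self, tag: str) -> list[str]:
        keep = self.metadata.index[self.metadata["tag"] == tag]
        return [c for c in self.intensities.columns if c in set(keep)]


def rollup_protein_intensity(
    peptides: pd.DataFrame,
    metadata: pd.DataFrame,
    bait_protein: str | None = None,
    bait_exclusion_region: tuple[int, int] | None = None,
) -> IntensityTable:
    """Sum peptide intensities to protein level.

    ``peptides`` needs columns ``protein, peptide, start, homologous`` plus
    one intensity column per sample.  Homologous peptides (shared across
    proteins) contribute to no protein.  For ``bait_protein``, peptides whose
    residue span ``[start, start+len)`` overlaps the half-open
    ``bait_exclusion_region`` are excluded before summation, so bait
    quantitation ignores the modified region.  Proteins with no surviving
    peptide are absent from the result (missing, not zero).
    """
    required = {"protein", "peptide", "start", "homologous"}
    if not required.issubset(peptides.columns):
        raise ValueError(f"peptide table lacks columns {sorted(required - set(peptides.columns))}")
    sample_cols = [c for c in peptides.columns if c not in required]
    kept = peptides.loc[~peptides["homologous"].astype(bool)].copy()
    if bait_protein is not None and bait_exclusion_region is not None:
        lo, hi = bait_exclusion_region
        pep_start = kept["start"].astype(int)
        pep_end = pep_start + kept["peptide"].str.len()
        overlaps = (kept["protein"] == bait_protein) & (pep_start < hi) & (pep_end > lo)
        kept = kept.loc[~overlaps]
    rolled = kept.groupby("protein", sort=False)[sample_cols].sum(min_count=1)
    return IntensityTable(rolled, metadata)


def _line_ratio(
    table: IntensityTable,
    num_cols: Sequence[str],
    den_cols: Sequence[str],
    mode: str,
    den_floor: float | None = None,
) -> pd.Series:
    """log2 enrichment of numerator samples over denominator samples.

    ``ratio_of_means`` (default): log2 of the ratio of replicate-mean
    intensities.  ``mean_of_ratios``: mean of log2 ratios over all numerator
    x denominator sample combinations.  ``den_floor`` substitutes for a
    denominator that is missing in every sample.
    """
    num = table.intensities[list(num_cols)]
    den = table.intensities[list(den_cols)]
    if mode == "ratio_of_means":
        num_mean = num.mean(axis=1)
        den_mean = den.mean(axis=1)
        if den_floor is not None:
            den_mean = den_mean.fillna(den_floor)
        return np.log2(num_mean / den_mean)
    if mode == "mean_of_ratios":
        log_num = np.log2(num).mean(axis=1)
        log_den = np.log2(den).mean(axis=1)
        if den_floor is not None:
            log_den = log_den.fillna(np.log2(den_floor))
        return log_num - log_den
    raise ValueError(f"unknown ratio mode {mode!r}")


def _normalize_and_z(values: pd.Series, context: str) -> tuple[pd.Series, pd.Series, bool]:
    """Median-centre, then z-score with the sample SD over scored proteins."""
    centred = values - values.median()
    sd = centred.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn(
            f"{context}: zero variance across proteins; no calls made", stacklevel=3
        )
        return centred, pd.Series(np.nan, index=values.index), True
    z = (centred - centred.mean()) / sd
    return centred, z, False


def specificity_score(
    table: IntensityTable,
    sd_threshold: float = 2.0,
    flag_tags: Iterable[str] = (TAG_FLAG_WT, TAG_FLAG_S248A),
    mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Call bait-specific interactors from FLAG/HA enrichment ratios.

    Proteins absent from every FLAG sample are not scored.  Proteins absent
    from every HA sample receive a floor intensity equal to the 1st
    percentile of observed HA intensities, keeping bait-specific preys
    scoreable without infinite ratios.

    Returns a DataFrame indexed by protein with columns ``log2_ratio``
    (FLAG over HA), ``normalized`` (median-centred), ``z`` and ``specific``
    (one-sided call at ``sd_threshold``).
    """
    flag_cols = [c for t in flag_tags for c in table.samples_with_tag(t)]
    ha_cols = table.samples_with_tag(TAG_HA)
    if not flag_cols or not ha_cols:
        raise ValueError("need at least one FLAG sample and one HA sample")
    ha_obs = table.intensities[ha_cols].to_numpy(dtype=float)
    ha_obs = ha_obs[np.isfinite(ha_obs)]
    floor = float(np.percentile(ha_obs, 1)) if ha_obs.size else np.nan
    scored = table.intensities[flag_cols].notna().any(axis=1)
    sub = IntensityTable(table.intensities.loc[scored], table.metadata)
    if len(sub.intensities) < 3:
        raise ValueError("need at least 3 scored proteins")
    r = _line_ratio(sub, flag_cols, ha_cols, mode, den_floor=floor)
    normalized, z, degenerate = _normalize_and_z(r, "specificity_score")
    specific = pd.Series(False, index=r.index) if degenerate else z >= sd_threshold
    return pd.DataFrame(
        {"log2_ratio": r, "normalized": normalized, "z": z, "specific": specific}
    )


def specific_interactors(
    table: IntensityTable, sd_threshold: float = 2.0, mode: str = "ratio_of_means"
) -> pd.Index:
    """Proteins passing the specificity call in *both* FLAG lines independently."""
    calls = []
    for tag in (TAG_FLAG_WT, TAG_FLAG_S248A):
        res = specificity_score(table, sd_threshold, flag_tags=(tag,), mode=mode)
        calls.append(set(res.index[res["specific"]]))
    both = calls[0] & calls[1]
    return pd.Index([p for p in table.intensities.index if p in both])


def differential_score(
    table: IntensityTable,
    z_threshold: float = 1.5,
    mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Classify interactors preferring the S248A or wild-type bait form.

    The statistic is the log2 ratio-of-ratios (S248A/HA over WT/HA); the HA
    term cancels, so it reduces to log2(S248A) - log2(WT).  After median
    centring, z > ``z_threshold`` is S248A-preferring, z < -``z_threshold``
    WT-preferring, otherwise shared.  Only proteins observed in at least one
    sample of each FLAG line are scored.
    """
    wt_cols = table.samples_with_tag(TAG_FLAG_WT)
    mut_cols = table.samples_with_tag(TAG_FLAG_S248A)
    if not wt_cols or not mut_cols:
        raise ValueError("need samples for both FLAG_WT and FLAG_S248A")
    scored = (
        table.intensities[wt_cols].notna().any(axis=1)
        & table.intensities[mut_cols].notna().any(axis=1)
    )
    sub = IntensityTable(table.intensities.loc[scored], table.metadata)
    d = _line_ratio(sub, mut_cols, wt_cols, mode)
    normalized, z, degenerate = _normalize_and_z(d, "differential_score")
    if degenerate:
        cls = pd.Series("shared", index=d.index)
    else:
        cls = pd.Series(
            np.select(
                [z > z_threshold, z < -z_threshold],
                ["S248A_preferring", "WT_preferring"],
                default="shared",
            ),
            index=d.index,
        )
    return pd.DataFrame(
        {
            "log2_ratio": d,
            "normalized": normalized,
            "z": z,
            "fold_change": 2.0**d,
            "class": cls,
        }
    )


def targeted_top2(
    peptides: pd.DataFrame,
    protein_list: Sequence[str],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Targeted quantitation from the top two most intense, non-homologous peptides.

    For each listed protein (e.g. a NuRD complex subunit) the two
    non-homologous peptides with the highest total intensity across all
    samples are selected; per replicate, enrichment is the log2 ratio of
    their summed FLAG_S248A intensity over their summed FLAG_WT intensity,
    and the median over replicates is reported.  Proteins with fewer than two
    eligible peptides are skipped with a warning.
    """
    sample_cols = [c for c in peptides.columns if c in set(metadata.index)]
    meta = metadata.loc[sample_cols]
    reps = sorted(meta["replicate"].unique())
    rows = []
    for prot in protein_list:
        eligible = peptides.loc[
            (peptides["protein"] == prot) & ~peptides["homologous"].astype(bool)
        ]
        if len(eligible) < 2:
            warnings.warn(f"{prot}: fewer than 2 eligible peptides; skipped")
            continue
        totals = eligible[sample_cols].sum(axis=1, skipna=True)
        top2 = eligible.loc[totals.sort_values(ascending=False).index[:2]]
        enrichments = []
        for rep in reps:
            mut_cols = meta.index[(meta["tag"] == TAG_FLAG_S248A) & (meta["replicate"] == rep)]
            wt_cols = meta.index[(meta["tag"] == TAG_FLAG_WT) & (meta["replicate"] == rep)]
            if len(mut_cols) == 0 or len(wt_cols) == 0:
                continue
            mut = top2[list(mut_cols)].sum().sum()
            wt = top2[list(wt_cols)].sum().sum()
            if mut > 0 and wt > 0:
                enrichments.append(np.log2(mut / wt))
        rows.append(
            {
                "protein": prot,
                "median_log2_enrichment": float(np.median(enrichments)) if enrichments else np.nan,
                "n_replicates": len(enrichments),
                "peptides": ";".join(top2["peptide"]),
            }
        )
    return pd.DataFrame(rows, columns=["protein", "median_log2_enrichment", "n_replicates", "peptides"])
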