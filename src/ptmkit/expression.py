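"""Simple expression computations: paired DE filtering and 2^-dCq quantitation.

Differential expression between paired WT and S248A cultures is called by a
fold-change gate combined with a per-gene paired t-test: the test is a
one-sample t on the per-pair log2 differences (two-sided), the fold change
is the geometric mean of per-pair ratios, and a gene is up iff
FC >= ``fc_cutoff`` and p < ``alpha`` (down for the reciprocal).  No
multiple-testing correction is applied by default, mirroring a raw
p < 0.05 gate; Benjamini-Hochberg q-values can be reported as an extra
column.  RT-qPCR relative quantitation uses 2^-(Cq(gene) - Cq(reference)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionMatrix", "de_filter", "delta_cq", "plot_volcano"]

CONDITIONS = ("WT", "S248A")


@dataclass
class ExpressionMatrix:
    """Gene x sample linear-scale expression values with paired metadata.

    ``values``: DataFrame indexed by gene, one column per sample, all
    positive.  ``metadata``: DataFrame indexed by sample with columns
    ``condition`` (WT or S248A) and ``pair`` (replicate-pair index); every
    pair must contain both conditions.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        bad = set(self.metadata["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        for pair, grp in self.metadata.groupby("pair"):
            if set(grp["condition"]) != set(CONDITIONS):
                raise ValueError(f"replicate pair {pair!r} lacks one condition")
        if (self.values.to_numpy(dtype=float) <= 0).any():
            raise ValueError("expression values must be positive (linear scale)")

    def paired_columns(self) -> list[tuple[str, str]]:
        """(WT sample, S248A sample) column names per replicate pair, in pair order."""
        pairs = []
        for pair in sorted(self.metadata["pair"].unique()):
            grp = self.metadata[self.metadata["pair"] == pair]
            wt = grp.index[grp["condition"] == "WT"][0]
            mut = grp.index[grp["condition"] == "S248A"][0]
            pairs.append((wt, mut))
        return pairs


def de_filter(
    matrix: ExpressionMatrix,
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
    fc_mode: str = "geometric",
    report_q: bool = False,
) -> pd.DataFrame:
    """Differential-expression filter: fold change gate + paired t-test.

    Returns a DataFrame indexed by gene with columns ``fold_change``
    (S248A over WT), ``t``, ``p``, ``class`` (up/down/unchanged) and
    ``degenerate`` (zero-variance differences with nonzero mean, where p is
    reported as the 0 limit).  ``fc_mode='arithmetic'`` uses the mean of
    per-pair ratios instead of the geometric mean.
    """
    pairs = matrix.paired_columns()
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs for a paired t-test")
    wt = matrix.values[[w for w, _ in pairs]].to_numpy(dtype=float)
    mut = matrix.values[[m for _, m in pairs]].to_numpy(dtype=float)
    diffs = np.log2(mut) - np.log2(wt)
    n = diffs.shape[1]
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = (sd_d == 0) & (mean_d != 0)
    p = np.where(degenerate, 0.0, p)
    t = np.where(degenerate, np.where(mean_d > 0, np.inf, -np.inf), t)
    all_same = (sd_d == 0) & (mean_d == 0)
    p = np.where(all_same, 1.0, p)
    t = np.where(all_same, 0.0, t)
    if fc_mode == "geometric":
        fc = 2.0**mean_d
    elif fc_mode == "arithmetic":
        fc = (mut / wt).mean(axis=1)
    else:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    cls = np.select(
        [(fc >= fc_cutoff) & (p < alpha), (fc <= 1.0 / fc_cutoff) & (p < alpha)],
        ["up", "down"],
        default="unchanged",
    )
    out = pd.DataFrame(
        {"fold_change": fc, "t": t, "p": p, "class": cls, "degenerate": degenerate},
        index=matrix.values.index,
    )
    if report_q:
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def delta_cq(cq_gene, cq_ref):
    """Relative expression by the 2^-(dCq) method, dCq = Cq(gene) - Cq(reference)."""
    return 2.0 ** -(np.asarray(cq_gene, dtype=float) - np.asarray(cq_ref, dtype=float))


def plot_volcano(de_table: pd.DataFrame, ax=None):
    """Basic volcano plot of a :func:`de_filter` result (log2 FC vs -log10 p)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.log2(de_table["fold_change"])
    y = -np.log10(np.clip(de_table["p"], 1e-300, None))
    colors = de_table["class"].map({"up": "red", "down": "blue", "unchanged": "grey"})
    ax.scatter(x, y, s=4, c=colors)
    ax.set_xlabel("log2 fold change (S248A / WT)")
    ax.set_ylabel("-log10 p (paired t)")
    return ax
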