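"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: MS1 runs with
Gaussian elution profiles at theoretical proteoform m/z values, AP-MS LFQ
tables with background plus spiked bait-specific and differential
interactors, ChIP/input tag sets over a toy genome with enriched regions
and embedded motif instances, and paired expression matrices with planted
fold changes.  Each generator is bit-reproducible for a fixed seed and
returns a ``truth`` object sufficient to score downstream recovery without
re-reading generator internals.

The generators model the statistics the downstream operations rely on, not
instrument physics: elution peaks are Gaussian (real peaks tail, but the
integrator is shape-agnostic), AP-MS intensities are log-normal, and ChIP
tags are single-position events without a fragment model.
"""

from __future__ import annotations

import string
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip_signal import PWM, TagSet, reverse_complement
from .expression import ExpressionMatrix
from .interactome import TAG_FLAG_S248A, TAG_FLAG_WT, TAG_HA, IntensityTable
from .ptm_quant import MS1Run, ModifiedPeptide, Scan

__all__ = ["gen_ms1_run", "gen_apms", "gen_chip", "gen_expression"]

#: truth rt windows extend this many elution sigmas either side of the center
_RT_HALF_WIDTH_SIGMAS = 6.0


def gen_ms1_run(
    isoforms: Sequence[ModifiedPeptide],
    fractions: Mapping[str, float],
    peak_rt_centers: Mapping[str, float],
    peak_width: float = 0.1,
    total_area: float = 1e6,
    noise_cv: float = 0.01,
    seed: int | np.random.Generator = 0,
    scan_interval: float = 0.02,
    mz_range: tuple[float, float] = (400.0, 1600.0),
    background_rate: float = 5.0,
) -> tuple[MS1Run, dict]:
    """Simulate an MS1 run containing a cluster of PTM isoform elution peaks.

    Each isoform label elutes as a Gaussian profile (sd ``peak_width``
    minutes) centred at its ``peak_rt_centers`` entry, with integrated area
    ``fractions[label] * total_area`` split evenly across that label's
    charge states.  Centroids are placed at the theoretical m/z with a
    sub-tolerance jitter (uniform +-3 ppm); intensities carry multiplicative
    Gaussian noise with coefficient of variation ``noise_cv``.  Poisson
    background centroids (mean ``background_rate`` per scan) are drawn
    away from all targets (>= 50 ppm).

    Returns the run and a truth dict with keys ``fractions``,
    ``rt_windows`` (±6 sd, guaranteed disjoint for isobaric labels) and
    ``mz`` per label.
    """
    rng = np.random.default_rng(seed)
    labels = list(fractions)
    fr = np.array([fractions[lbl] for lbl in labels], dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be non-negative and sum to 1")
    by_label = {lbl: [p for p in isoforms if p.label == lbl] for lbl in labels}
    for lbl, peps in by_label.items():
        if not peps:
            raise ValueError(f"no ModifiedPeptide provided for isoform {lbl!r}")
        if lbl not in peak_rt_centers:
            raise ValueError(f"no rt center for isoform {lbl!r}")
    half = _RT_HALF_WIDTH_SIGMAS * peak_width
    windows = {lbl: (peak_rt_centers[lbl] - half, peak_rt_centers[lbl] + half) for lbl in labels}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            wa, wb = windows[la], windows[lb]
            if wa[0] < wb[1] and wb[0] < wa[1]:
                isobaric = any(
                    abs(pa.mz - pb.mz) <= 20e-6 * pa.mz
                    for pa in by_label[la]
                    for pb in by_label[lb]
                )
                if isobaric:
                    raise ValueError(
                        f"isobaric isoforms {la!r} and {lb!r} have overlapping "
                        "elution windows; give them distinct rt centers"
                    )

    target_mz = np.array([p.mz for peps in by_label.values() for p in peps])
    rt_lo = min(w[0] for w in windows.values()) - 0.5
    rt_hi = max(w[1] for w in windows.values()) + 0.5
    rts = np.arange(rt_lo, rt_hi + scan_interval / 2, scan_interval)
    norm = 1.0 / (peak_width * np.sqrt(2.0 * np.pi))
    scans = []
    for rt in rts:
        mzs: list[float] = []
        intens: list[float] = []
        for lbl, frac in zip(labels, fr):
            c = peak_rt_centers[lbl]
            if abs(rt - c) > half:
                continue
            profile = norm * np.exp(-0.5 * ((rt - c) / peak_width) ** 2)
            per_charge = frac * total_area / len(by_label[lbl])
            for pep in by_label[lbl]:
                y = per_charge * profile
                if noise_cv > 0:
                    y *= max(0.0, 1.0 + rng.normal(0.0, noise_cv))
                mz = pep.mz * (1.0 + rng.uniform(-3e-6, 3e-6))
                mzs.append(mz)
                intens.append(y)
        n_bg = rng.poisson(background_rate)
        drawn = 0
        while drawn < n_bg:
            mz = rng.uniform(*mz_range)
            if np.all(np.abs(mz - target_mz) > 50e-6 * target_mz):
                mzs.append(mz)
                intens.append(rng.exponential(total_area * 1e-4))
                drawn += 1
        order = np.argsort(mzs)
        scans.append(Scan(float(rt), np.array(mzs)[order], np.array(intens)[order]))
    truth = {
        "fractions": dict(zip(labels, fr)),
        "rt_windows": windows,
        "mz": {lbl: [p.mz for p in peps] for lbl, peps in by_label.items()},
    }
    return MS1Run(scans), truth


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 15) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(_AA), size=n))


def gen_apms(
    n_background: int = 200,
    specific_interactors: Sequence[tuple[float, float]] = ((16.0, 1.0), (16.0, 4.0), (16.0, 0.25)),
    log2_noise_sd: float = 0.5,
    n_replicates: int = 2,
    missing_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, IntensityTable, pd.DataFrame]:
    """Simulate an AP-MS co-IP experiment (FLAG_WT, FLAG_S248A, HA lines).

    Background proteins have FLAG/HA intensity ratios centred at 1; each
    ``(fold, differential_fold)`` entry adds a bait-specific interactor at
    ``fold`` over HA in both FLAG lines, with the FLAG_S248A line further
    scaled by ``differential_fold``.  Sample noise is log-normal
    (``log2_noise_sd`` in log2 units) and values are dropped (NaN) at
    ``missing_rate``.  Spiked proteins are never dropped so every planted
    effect remains scoreable.

    Returns ``(peptide table, IntensityTable, truth)``.  Non-homologous
    peptide intensities sum exactly to the protein intensity; a few extra
    homologous peptides (shared between two proteins) are appended and
    flagged.  Truth columns: ``fold, differential_fold, is_specific,
    preferred``.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    proteins = [f"BG{i:04d}" for i in range(n_background)]
    folds = [1.0] * n_background
    dfolds = [1.0] * n_background
    for i, (fold, dfold) in enumerate(specific_interactors):
        proteins.append(f"SPIKE{i:02d}")
        folds.append(float(fold))
        dfolds.append(float(dfold))
    folds_arr = np.array(folds)
    dfolds_arr = np.array(dfolds)
    n = len(proteins)
    base = 2.0 ** rng.normal(20.0, 2.0, size=n)

    samples, tags, reps = [], [], []
    for tag in (TAG_FLAG_WT, TAG_FLAG_S248A, TAG_HA):
        for r in range(1, n_replicates + 1):
            samples.append(f"{tag}_r{r}")
            tags.append(tag)
            reps.append(r)
    metadata = pd.DataFrame({"tag": tags, "replicate": reps}, index=pd.Index(samples, name="sample"))

    mean_level = {
        TAG_HA: base,
        TAG_FLAG_WT: base * folds_arr,
        TAG_FLAG_S248A: base * folds_arr * dfolds_arr,
    }
    intens = {}
    for sample, tag in zip(samples, tags):
        noise = 2.0 ** rng.normal(0.0, log2_noise_sd, size=n)
        intens[sample] = mean_level[tag] * noise
    table = pd.DataFrame(intens, index=pd.Index(proteins, name="protein"))
    if missing_rate > 0:
        drop = rng.random(table.shape) < missing_rate
        drop[n_background:, :] = False  # keep spiked interactors observable
        table = table.mask(drop)

    pep_rows = []
    for i, prot in enumerate(proteins):
        k = int(rng.integers(3, 7))
        shares = rng.dirichlet(np.ones(k))
        start = 0
        for share in shares:
            pep = _random_peptide(rng)
            row = {"protein": prot, "peptide": pep, "start": start, "homologous": False}
            for sample in samples:
                row[sample] = table.loc[prot, sample] * share
            pep_rows.append(row)
            start += len(pep) + int(rng.integers(1, 20))
    # homologous peptides: shared verbatim between two proteins, flagged,
    # carrying extra intensity that must not reach protein level
    for _ in range(max(2, n // 100)):
        pa, pb = rng.choice(n, size=2, replace=False)
        pep = _random_peptide(rng)
        for p in (pa, pb):
            row = {
                "protein": proteins[p],
                "peptide": pep,
                "start": 0,
                "homologous": True,
            }
            for sample in samples:
                row[sample] = float(rng.exponential(2.0**18))
            pep_rows.append(row)
    peptides = pd.DataFrame(pep_rows)

    truth = pd.DataFrame(
        {
            "fold": folds_arr,
            "differential_fold": dfolds_arr,
            "is_specific": folds_arr > 1.0,
            "preferred": np.select(
                [dfolds_arr > 1.0, dfolds_arr < 1.0],
                ["S248A_preferring", "WT_preferring"],
                default="shared",
            ),
        },
        index=pd.Index(proteins, name="protein"),
    )
    return peptides, IntensityTable(table, metadata), truth


def gen_chip(
    genome_length: int = 100_000,
    n_chroms: int = 2,
    n_true_regions: int = 20,
    region_width: int = 300,
    enrichment_fold: float = 10.0,
    n_chip_tags: int = 20_000,
    n_input_tags: int = 20_000,
    motif: str = "CTTTGTTATGCAAAT",
    motif_fraction_true: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, str], TagSet, TagSet, pd.DataFrame]:
    """Simulate a toy genome with enriched ChIP regions and embedded motifs.

    Background ChIP tags fall uniformly over the genome; within each of the
    ``n_true_regions`` enriched regions the tag rate is ``enrichment_fold``
    times background.  A composite-motif consensus is written into a stated
    fraction of the regions (random strand).  Input tags are uniform.

    Returns ``(genome, chip TagSet, input TagSet, truth)`` where truth lists
    each region's interval, motif flag and motif strand.
    """
    rng = np.random.default_rng(seed)
    if region_width > genome_length:
        raise ValueError("region_width exceeds chromosome length")
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    sizes = {c: genome_length for c in chrom_names}
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=genome_length)) for c in chrom_names
    }

    # non-overlapping enriched regions, spread across chromosomes
    regions = []
    per_chrom = np.array_split(np.arange(n_true_regions), n_chroms)
    for c_idx, chunk in enumerate(per_chrom):
        k = len(chunk)
        if k == 0:
            continue
        slot = genome_length // k
        if slot < 2 * region_width:
            raise ValueError("too many regions for the genome size")
        for j in range(k):
            start = j * slot + int(rng.integers(0, slot - region_width))
            regions.append({"chrom": chrom_names[c_idx], "start": start, "end": start + region_width})
    regions = pd.DataFrame(regions)

    n_with_motif = int(round(motif_fraction_true * len(regions)))
    motif_idx = rng.choice(len(regions), size=n_with_motif, replace=False)
    has_motif = np.zeros(len(regions), dtype=bool)
    has_motif[motif_idx] = True
    strands = np.where(rng.random(len(regions)) < 0.5, "+", "-")
    for i in np.flatnonzero(has_motif):
        row = regions.iloc[i]
        insert = motif if strands[i] == "+" else reverse_complement(motif)
        offset = int(row.start + (region_width - len(motif)) // 2)
        g = genome[row.chrom]
        genome[row.chrom] = g[:offset] + insert + g[offset + len(insert) :]
    truth = regions.copy()
    truth["has_motif"] = has_motif
    truth["motif_strand"] = np.where(has_motif, strands, ".")

    total_bp = n_chroms * genome_length
    region_bp = region_width * len(regions)
    p_region = (enrichment_fold * region_bp) / (
        enrichment_fold * region_bp + (total_bp - region_bp)
    )

    def _uniform_tags(count: int) -> pd.DataFrame:
        chrom_idx = rng.integers(0, n_chroms, size=count)
        pos = rng.integers(0, genome_length, size=count)
        strand = np.where(rng.random(count) < 0.5, "+", "-")
        return pd.DataFrame(
            {"chrom": np.array(chrom_names)[chrom_idx], "pos": pos, "strand": strand}
        )

    in_region = rng.random(n_chip_tags) < p_region
    n_in = int(in_region.sum())
    bg = _uniform_tags(n_chip_tags - n_in)
    reg_choice = rng.integers(0, len(regions), size=n_in)
    reg_pos = regions["start"].to_numpy()[reg_choice] + rng.integers(0, region_width, size=n_in)
    reg_tags = pd.DataFrame(
        {
            "chrom": regions["chrom"].to_numpy()[reg_choice],
            "pos": reg_pos,
            "strand": np.where(rng.random(n_in) < 0.5, "+", "-"),
        }
    )
    chip = pd.concat([bg, reg_tags], ignore_index=True).sort_values(["chrom", "pos"]).reset_index(drop=True)
    input_tags = _uniform_tags(n_input_tags).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return genome, TagSet(chip, sizes), TagSet(input_tags, sizes), truth


def gen_expression(
    n_genes: int = 12_000,
    n_up: int = 320,
    n_down: int = 344,
    fold: float = 2.0,
    n_pairs: int = 3,
    log2_noise_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a paired WT/S248A expression matrix with planted fold changes.

    The first ``n_up`` genes are up ``fold``-fold in S248A, the next
    ``n_down`` genes down, the remainder null.  A shared per-gene, per-pair
    batch effect induces the pairing structure; residual noise is log-normal
    with sd ``log2_noise_sd`` (log2 units).
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    direction = np.zeros(n_genes)
    direction[:n_up] = 1.0
    direction[n_up : n_up + n_down] = -1.0
    log2_fc = direction * np.log2(fold)
    base = rng.normal(8.0, 2.0, size=n_genes)
    pair_effect = rng.normal(0.0, 0.25, size=(n_genes, n_pairs))

    values = {}
    samples, conditions, pairs = [], [], []
    for p in range(1, n_pairs + 1):
        for cond in ("WT", "S248A"):
            name = f"{cond}_p{p}"
            shift = log2_fc if cond == "S248A" else 0.0
            noise = rng.normal(0.0, log2_noise_sd, size=n_genes)
            values[name] = 2.0 ** (base + pair_effect[:, p - 1] + shift + noise)
            samples.append(name)
            conditions.append(cond)
            pairs.append(p)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene")),
        pd.DataFrame(
            {"condition": conditions, "pair": pairs}, index=pd.Index(samples, name="sample")
        ),
    )
    truth = pd.DataFrame(
        {
            "class": np.select([direction > 0, direction < 0], ["up", "down"], default="unchanged"),
            "log2_fold_change": log2_fc,
        },
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth
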