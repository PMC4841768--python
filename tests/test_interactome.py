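"""AP-MS specificity and differential-interaction scoring."""

import numpy as np
import pandas as pd
import pytest

from ptmkit.interactome import (
    TAG_FLAG_S248A,
    TAG_FLAG_WT,
    TAG_HA,
    IntensityTable,
    differential_score,
    rollup_protein_intensity,
    specificity_score,
    targeted_top2,
)


def make_table(values: dict, n_reps: int = 1) -> IntensityTable:
    """values: protein -> {tag: intensity or [per-rep intensities]}."""
    samples, tags, reps = [], [], []
    for tag in (TAG_FLAG_WT, TAG_FLAG_S248A, TAG_HA):
        for r in range(1, n_reps + 1):
            samples.append(f"{tag}_r{r}")
            tags.append(tag)
            reps.append(r)
    meta = pd.DataFrame({"tag": tags, "replicate": reps}, index=pd.Index(samples, name="sample"))
    rows = {}
    for prot, by_tag in values.items():
        row = []
        for tag, rep in zip(tags, reps):
            v = by_tag[tag]
            row.append(v[rep - 1] if isinstance(v, (list, tuple)) else v)
        rows[prot] = row
    return IntensityTable(pd.DataFrame.from_dict(rows, orient="index", columns=samples), meta)


class TestSpecificity:
    def test_hand_computed_five_protein_example(self):
        # FLAG/HA ratios {1,1,1,1,16} -> log2 ratios {0,0,0,0,4}; median 0;
        # mean 0.8, sd(ddof=1) = sqrt(4*0.64+10.24)/2 = sqrt(3.2); z = 3.2/1.789 = 1.789
        vals = {f"p{i}": {TAG_FLAG_WT: 100.0, TAG_FLAG_S248A: 100.0, TAG_HA: 100.0} for i in range(4)}
        vals["hit"] = {TAG_FLAG_WT: 1600.0, TAG_FLAG_S248A: 1600.0, TAG_HA: 100.0}
        res = specificity_score(make_table(vals), sd_threshold=1.7)
        r = res.loc["hit"]
        assert r["log2_ratio"] == pytest.approx(4.0)
        expected_z = (4.0 - 0.8) / np.std([0, 0, 0, 0, 4], ddof=1)
        assert r["z"] == pytest.approx(expected_z)
        assert bool(r["specific"])
        assert not res.loc[[f"p{i}" for i in range(4)], "specific"].any()

    def test_flag_equal_ha_protein_is_background(self):
        vals = {f"p{i}": {TAG_FLAG_WT: 50.0 * (i + 1), TAG_FLAG_S248A: 50.0 * (i + 1), TAG_HA: 50.0 * (i + 1)}
                for i in range(5)}
        vals["hit"] = {TAG_FLAG_WT: 3200.0, TAG_FLAG_S248A: 3200.0, TAG_HA: 100.0}
        res = specificity_score(make_table(vals))
        assert res.loc["p0", "log2_ratio"] == pytest.approx(0.0)
        assert not bool(res.loc["p0", "specific"])

    def test_zero_variance_warns_and_makes_no_calls(self):
        vals = {f"p{i}": {TAG_FLAG_WT: 100.0, TAG_FLAG_S248A: 100.0, TAG_HA: 100.0} for i in range(5)}
        with pytest.warns(UserWarning, match="zero variance"):
            res = specificity_score(make_table(vals))
        assert not res["specific"].any()

    def test_median_of_normalized_ratios_is_zero(self):
        rng = np.random.default_rng(0)
        vals = {
            f"p{i}": {TAG_FLAG_WT: v, TAG_FLAG_S248A: v * rng.uniform(0.5, 2), TAG_HA: 100.0}
            for i, v in enumerate(rng.uniform(50, 5000, size=21))
        }
        res = specificity_score(make_table(vals))
        assert res["normalized"].median() == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance_under_global_rescaling(self):
        rng = np.random.default_rng(1)
        vals = {
            f"p{i}": {
                TAG_FLAG_WT: rng.uniform(10, 1e4),
                TAG_FLAG_S248A: rng.uniform(10, 1e4),
                TAG_HA: rng.uniform(10, 1e4),
            }
            for i in range(30)
        }
        t1 = make_table(vals)
        t2 = IntensityTable(t1.intensities * 1000.0, t1.metadata)
        for fn in (specificity_score, differential_score):
            a, b = fn(t1), fn(t2)
            pd.testing.assert_series_equal(a["z"], b["z"], atol=1e-9, rtol=0)

    def test_row_permutation_does_not_change_calls(self):
        rng = np.random.default_rng(2)
        vals = {
            f"p{i}": {TAG_FLAG_WT: rng.uniform(10, 1e4), TAG_FLAG_S248A: rng.uniform(10, 1e4), TAG_HA: 100.0}
            for i in range(20)
        }
        t1 = make_table(vals)
        perm = t1.intensities.sample(frac=1.0, random_state=3)
        t2 = IntensityTable(perm, t1.metadata)
        a = specificity_score(t1).sort_index()
        b = specificity_score(t2).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_protein_absent_from_ha_floored_not_infinite(self):
        vals = {f"p{i}": {TAG_FLAG_WT: 100.0 + i, TAG_FLAG_S248A: 100.0, TAG_HA: 100.0} for i in range(5)}
        vals["prey"] = {TAG_FLAG_WT: 5000.0, TAG_FLAG_S248A: 5000.0, TAG_HA: np.nan}
        res = specificity_score(make_table(vals))
        assert np.isfinite(res.loc["prey", "log2_ratio"])
        assert bool(res.loc["prey", "specific"])


class TestDifferential:
    def test_identical_flag_lines_are_shared(self):
        rng = np.random.default_rng(4)
        vals = {
            f"p{i}": {TAG_FLAG_WT: v, TAG_FLAG_S248A: v * rng.uniform(0.9, 1.1), TAG_HA: 100.0}
            for i, v in enumerate(rng.uniform(100, 1000, 20))
        }
        vals["same"] = {TAG_FLAG_WT: 500.0, TAG_FLAG_S248A: 500.0, TAG_HA: 100.0}
        res = differential_score(make_table(vals))
        assert res.loc["same", "log2_ratio"] == pytest.approx(0.0)
        assert res.loc["same", "class"] == "shared"

    def test_fourfold_s248a_enrichment_gives_raw_ratio_two(self):
        vals = {f"p{i}": {TAG_FLAG_WT: 100.0, TAG_FLAG_S248A: 110.0 + i, TAG_HA: 100.0} for i in range(5)}
        vals["hit"] = {TAG_FLAG_WT: 200.0, TAG_FLAG_S248A: 800.0, TAG_HA: 100.0}
        res = differential_score(make_table(vals))
        assert res.loc["hit", "log2_ratio"] == pytest.approx(2.0)

    def test_degenerate_table_all_shared_with_warning(self):
        vals = {f"p{i}": {TAG_FLAG_WT: 100.0, TAG_FLAG_S248A: 100.0, TAG_HA: 50.0} for i in range(4)}
        with pytest.warns(UserWarning):
            res = differential_score(make_table(vals))
        assert (res["class"] == "shared").all()


class TestRollup:
    @staticmethod
    def _peptides():
        return pd.DataFrame(
            {
                "protein": ["bait", "bait", "bait", "other", "other"],
                "peptide": ["SSPPVVTSS", "AAAAAAA", "CCCCC", "DDDD", "DDDD"],
                "start": [240, 10, 30, 0, 0],
                "homologous": [False, False, False, True, True],
                "s1": [500.0, 300.0, 200.0, 99.0, 99.0],
            }
        )

    @staticmethod
    def _meta():
        return pd.DataFrame(
            {"tag": [TAG_FLAG_WT], "replicate": [1]}, index=pd.Index(["s1"], name="sample")
        )

    def test_bait_region_peptides_excluded_from_bait_sum(self):
        table = rollup_protein_intensity(
            self._peptides(), self._meta(), bait_protein="bait", bait_exclusion_region=(235, 265)
        )
        assert table.intensities.loc["bait", "s1"] == 500.0  # 300 + 200

    def test_without_exclusion_plain_sum(self):
        table = rollup_protein_intensity(self._peptides(), self._meta())
        assert table.intensities.loc["bait", "s1"] == 1000.0

    def test_homologous_peptides_contribute_to_no_protein(self):
        table = rollup_protein_intensity(self._peptides(), self._meta())
        assert "other" not in table.intensities.index  # its only peptide was shared


class TestTargetedTop2:
    @staticmethod
    def _setup():
        samples = ["FLAG_WT_r1", "FLAG_S248A_r1", "FLAG_WT_r2", "FLAG_S248A_r2", "FLAG_WT_r3", "FLAG_S248A_r3"]
        meta = pd.DataFrame(
            {
                "tag": [TAG_FLAG_WT, TAG_FLAG_S248A] * 3,
                "replicate": [1, 1, 2, 2, 3, 3],
            },
            index=pd.Index(samples, name="sample"),
        )
        peptides = pd.DataFrame(
            {
                "protein": ["nurd"] * 4,
                "peptide": ["TOPONE", "HOMOLOG", "TOPTWO", "WEAK"],
                "start": [0, 20, 40, 60],
                "homologous": [False, True, False, False],
                # per-replicate S248A/WT ratios of top-2 sums: 2^0.8, 2^1.0, 2^3.0
                "FLAG_WT_r1": [100.0, 1e6, 80.0, 10.0],
                "FLAG_S248A_r1": [100.0 * 2**0.8, 1e6, 80.0 * 2**0.8, 10.0],
                "FLAG_WT_r2": [100.0, 1e6, 80.0, 10.0],
                "FLAG_S248A_r2": [200.0, 1e6, 160.0, 10.0],
                "FLAG_WT_r3": [100.0, 1e6, 80.0, 10.0],
                "FLAG_S248A_r3": [800.0, 1e6, 640.0, 10.0],
            }
        )
        return peptides, meta

    def test_top_two_selected_skipping_homologous_and_median_reported(self):
        peptides, meta = self._setup()
        res = targeted_top2(peptides, ["nurd"], meta)
        assert set(res.loc[0, "peptides"].split(";")) == {"TOPONE", "TOPTWO"}
        assert res.loc[0, "median_log2_enrichment"] == pytest.approx(1.0)

    def test_protein_with_too_few_peptides_skipped_with_warning(self):
        peptides, meta = self._setup()
        lone = peptides.iloc[[0]].assign(protein="lonely")
        with pytest.warns(UserWarning, match="lonely"):
            res = targeted_top2(pd.concat([peptides, lone]), ["lonely"], meta)
        assert res.empty
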