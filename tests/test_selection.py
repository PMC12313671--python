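"""Instrument-selection rules: thresholds, clumping, MAF, F, Steiger."""

import numpy as np
import pandas as pd
import pytest

from mrpath.selection import (
    LDMatrix,
    SelectionConfig,
    SelectionError,
    f_statistic,
    filter_f,
    filter_maf,
    ld_clump,
    select_by_pvalue,
    steiger_filter,
    variance_explained,
)
from mrpath.simulate import SimConfig, as_instrument_table, simulate_pair

from conftest import make_table


def _frame(pvals, eafs=None, chroms=None, positions=None, betas=None, ses=None):
    k = len(pvals)
    return pd.DataFrame(
        {
            "variant_id": [f"s{i+1}" for i in range(k)],
            "chrom": chroms or ["1"] * k,
            "pos": positions or list(range(100, 100 + k)),
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "eaf": eafs or [0.3] * k,
            "beta": betas or [0.1] * k,
            "se": ses or [0.01] * k,
            "pval": pvals,
            "n": [50_000] * k,
        }
    )


class TestPvalueSelection:
    def test_primary_threshold_used_when_enough_hits(self):
        sub, used = select_by_pvalue(_frame([1e-9, 1e-9, 1e-9, 0.5]))
        assert len(sub) == 3 and used == 5e-8

    def test_fallback_when_fewer_than_three_hits(self):
        sub, used = select_by_pvalue(_frame([1e-6, 1e-7, 0.5]))
        assert len(sub) == 2 and used == 1e-5

    def test_nothing_passes_returns_empty_at_fallback(self):
        sub, used = select_by_pvalue(_frame([0.9, 0.9, 0.9]))
        assert len(sub) == 0 and used == 1e-5


def _brute_force_clump(df, ld, cfg):
    """Independent greedy oracle: explicit candidate list, no vector tricks."""
    remaining = df.sort_values(["pval", "variant_id"]).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        survivors = []
        for other in remaining:
            same_chrom = other["chrom"] == index["chrom"]
            close = abs(other["pos"] - index["pos"]) <= cfg.clump_window_kb * 1000
            linked = ld.r2(index["variant_id"], other["variant_id"]) > cfg.clump_r2
            if not (same_chrom and close and linked):
                survivors.append(other)
        remaining = survivors
    return [v for v in df["variant_id"] if v in kept]


class TestClumping:
    def test_three_snp_example_keeps_index_and_independent(self):
        df = _frame([1e-10, 1e-9, 1e-8], positions=[100_000, 150_000, 200_000])
        ld = LDMatrix(["s1", "s2", "s3"], {(0, 1): 0.5, (0, 2): 0.0005, (1, 2): 0.0005})
        out = ld_clump(df, ld)
        assert list(out["variant_id"]) == ["s1", "s3"]

    def test_unlinked_snps_all_retained(self):
        df = _frame([1e-10, 1e-9, 1e-8])
        ld = LDMatrix(["s1", "s2", "s3"])
        assert list(ld_clump(df, ld)["variant_id"]) == ["s1", "s2", "s3"]

    def test_distant_snps_escape_window(self):
        df = _frame([1e-10, 1e-9], positions=[1, 20_000_001])  # 20,000 kb apart
        ld = LDMatrix(["s1", "s2"], {(0, 1): 0.9})
        assert list(ld_clump(df, ld)["variant_id"]) == ["s1", "s2"]

    def test_missing_variant_is_fatal_and_named(self):
        df = _frame([1e-10, 1e-9])
        ld = LDMatrix(["s1"])
        with pytest.raises(SelectionError, match="s2"):
            ld_clump(df, ld)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        cfg = SelectionConfig()
        for _ in range(25):
            k = int(rng.integers(3, 12))
            df = _frame(
                list(rng.uniform(1e-12, 1e-6, k)),
                chroms=list(rng.choice(["1", "2"], k)),
                positions=list(rng.integers(1, 30_000_000, k)),
            )
            pairs = {
                (i, j): float(rng.uniform(0, 1)) if rng.random() < 0.4 else 0.0
                for i in range(k)
                for j in range(i + 1, k)
            }
            ld = LDMatrix(list(df["variant_id"]), pairs)
            assert list(ld_clump(df, ld, cfg)["variant_id"]) == _brute_force_clump(df, ld, cfg)

    def test_retained_set_is_ld_independent(self):
        bundle = simulate_pair(SimConfig(n_snps=60, ld_block_size=5, ld_rho=0.8, seed=4))
        cfg = SelectionConfig(clump_window_kb=100_000)
        out = ld_clump(bundle.exposure, bundle.ld, cfg)
        ids = list(out["variant_id"])
        pos = dict(zip(out["variant_id"], out["pos"]))
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if abs(pos[a] - pos[b]) <= cfg.clump_window_kb * 1000:
                    assert bundle.ld.r2(a, b) <= cfg.clump_r2


class TestMafAndF:
    @pytest.mark.parametrize("eaf,kept", [(0.005, False), (0.995, False), (0.30, True)])
    def test_maf_filter_is_symmetric(self, eaf, kept):
        out = filter_maf(_frame([1e-9], eafs=[eaf]))
        assert (len(out) == 1) is kept

    def test_f_statistic_values(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.02, 0.01) == pytest.approx(4.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_weak_instruments_removed(self):
        df = _frame([1e-9, 1e-9], betas=[0.1, 0.02], ses=[0.02, 0.01])
        assert list(filter_f(df)["variant_id"]) == ["s1"]

    def test_f_statistic_rejects_bad_se(self):
        with pytest.raises(SelectionError):
            f_statistic(0.1, 0.0)


class TestVarianceExplained:
    def test_null_effect_explains_nothing(self):
        assert variance_explained(0.0, 0.3, 0.01, 10_000) == 0.0

    def test_closed_form_hand_value(self):
        # 0.01*0.5 / (0.01*0.5 + 0.0001*0.5*10000) = 0.005/0.505
        assert variance_explained(0.1, 0.5, 0.01, 10_000) == pytest.approx(0.005 / 0.505)

    def test_monotone_in_effect_size(self):
        r2 = [variance_explained(b, 0.3, 0.01, 10_000) for b in (0.05, 0.1, 0.2, 0.4)]
        assert all(x < y for x, y in zip(r2, r2[1:]))

    def test_domain_errors(self):
        with pytest.raises(SelectionError):
            variance_explained(0.1, 1.2, 0.01, 10_000)
        with pytest.raises(SelectionError):
            variance_explained(0.1, 0.3, 0.01, 3)


class TestSteiger:
    def test_exposure_first_snp_retained(self):
        # strong exposure effect, weak outcome effect
        t = make_table([0.1], [0.005], [0.01], [0.005])
        kept, recs = steiger_filter(t)
        assert kept.n_snps == 1 and recs[0].direction_ok

    def test_equal_r2_is_removed_at_boundary(self):
        t = make_table([0.1], [0.01], [0.1], [0.01])
        kept, recs = steiger_filter(t)
        assert kept.n_snps == 0
        assert recs[0].z == pytest.approx(0.0)
        assert not recs[0].direction_ok

    def test_never_removes_exposure_dominant_snp(self, rng):
        t = make_table(
            rng.uniform(0.05, 0.3, 20), np.full(20, 0.005),
            rng.uniform(0.0, 0.01, 20), np.full(20, 0.005),
        )
        kept, recs = steiger_filter(t)
        for r in recs:
            if r.r2_exp > r.r2_out:
                assert r.direction_ok
        assert kept.n_snps == sum(r.direction_ok for r in recs)

    def test_null_outcome_retains_nearly_all_instruments(self):
        """Genome-wide-significant SNPs affecting only the exposure survive
        Steiger filtering (the filter runs on selected instruments)."""
        kept = total = 0
        for seed in range(40):
            bundle = simulate_pair(SimConfig(seed=seed, theta=0.0, n_exp=20_000, n_out=20_000))
            table = as_instrument_table(bundle)
            selected = (table.data["pval_exp"] < 5e-8).to_numpy()
            table = table.subset(selected)
            filtered, _ = steiger_filter(table)
            kept += filtered.n_snps
            total += table.n_snps
        assert kept / total >= 0.99

    def test_small_samples_rejected(self):
        t = make_table([0.1], [0.01], [0.01], [0.01], n_exp=2)
        with pytest.raises(SelectionError):
            steiger_filter(t)


class TestConfig:
    def test_invalid_configs_raise(self):
        with pytest.raises(SelectionError):
            SelectionConfig(p_primary=1e-4, p_fallback=1e-5)
        with pytest.raises(SelectionError):
            SelectionConfig(clump_r2=1.5)
        with pytest.raises(SelectionError):
            SelectionConfig(maf_min=0.7)

    def test_config_round_trips_through_key_value_file(self, tmp_path):
        cfg = SelectionConfig(p_primary=1e-6, clump_r2=0.01, maf_min=0.05)
        path = tmp_path / "cfg.txt"
        path.write_text(
            "p_primary = 1e-6\nclump_r2 = 0.01\nmaf_min = 0.05\n# comment\n"
        )
        assert SelectionConfig.from_file(path) == cfg
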