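"""EHH decay, marker-H selection, REHH and LRH standardization."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.ehh_scan import (
    EhhCurve,
    ehh,
    combined_ehh,
    marker_h,
    rehh,
    lrh_scan,
    standardize_lrh,
)
from sweepscan.simdata import SimConfig, simulate_two_pop, SweepLostError

from conftest import make_hapset


def ehh_pairwise_oracle(haps, rows, core, marker):
    """EHH by testing every haplotype pair for identity over the
    interval [core..marker] (O(c^2 M))."""
    lo, hi = min(core, marker), max(core, marker)
    c = len(rows)
    if c < 2:
        return float("nan")
    same = 0
    for x in range(c):
        for y in range(x + 1, c):
            if all(haps[rows[x], j] == haps[rows[y], j] for j in range(lo, hi + 1)):
                same += 1
    return same / (c * (c - 1) / 2)


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.zeros((6, 5), dtype=np.int8)
        haps[:4, 2] = 1  # 4 carriers, identical everywhere
        haps[4:, 0] = 1
        curve = ehh(make_hapset(haps), core=2, allele=1, direction="right")
        assert np.all(curve.values == 1.0)

    def test_two_two_split_gives_one_third(self):
        # 4 carriers split 2/2 at the first flanking marker:
        # EHH = (C(2,2)... pairs) = (1 + 1) / 6
        haps = np.zeros((8, 3), dtype=np.int8)
        haps[:4, 1] = 1          # carriers of allele 1 at core 1
        haps[0:2, 2] = 1         # two carriers split off at the right marker
        curve = ehh(make_hapset(haps), core=1, allele=1, direction="right")
        assert curve.values[0] == 1.0
        assert curve.values[1] == pytest.approx(2 / 6)

    def test_requires_two_carriers(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        haps[0, 1] = 1
        with pytest.raises(ValueError, match="carriers"):
            ehh(make_hapset(haps), core=1, allele=1, direction="right")

    def test_monotone_nonincreasing_and_bounded(self, random_hapset):
        for core in (0, 10, 29):
            for allele in (0, 1):
                rows = np.nonzero(random_hapset.haps[:, core] == allele)[0]
                if rows.size < 2:
                    continue
                for direction in ("left", "right"):
                    curve = ehh(random_hapset, core, allele, direction)
                    assert curve.values[0] == 1.0
                    assert np.all(np.diff(curve.values) <= 1e-12)
                    assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 21)) * 2
            m = int(rng.integers(3, 31))
            haps = (rng.random((n, m)) < rng.uniform(0.2, 0.8, m)).astype(np.int8)
            hs = make_hapset(haps)
            core = int(rng.integers(0, m))
            allele = int(rng.integers(0, 2))
            rows = np.nonzero(haps[:, core] == allele)[0]
            if rows.size < 2:
                continue
            direction = "right" if rng.random() < 0.5 else "left"
            curve = ehh(hs, core, allele, direction, max_dist=None)
            for k, mk in enumerate(curve.marker_idx):
                assert curve.values[k] == pytest.approx(
                    ehh_pairwise_oracle(haps, rows, core, int(mk)), abs=1e-12
                )


class TestMarkerH:
    def make_curve(self, values):
        n = len(values)
        return EhhCurve(
            core=0,
            allele=None,
            direction="right",
            marker_idx=np.arange(n),
            distance_bp=np.arange(n) * 10_000,
            values=np.asarray(values),
        )

    def test_exact_hit_selected(self):
        assert marker_h(self.make_curve([1.0, 0.5, 0.04, 0.01])) == 2

    def test_never_entering_band_returns_none(self):
        assert marker_h(self.make_curve([1.0, 0.5, 0.3, 0.06])) is None

    def test_first_marker_in_band_wins(self):
        assert marker_h(self.make_curve([1.0, 0.049, 0.031, 0.02])) == 1

    def test_respects_max_distance(self):
        curve = EhhCurve(
            core=0,
            allele=None,
            direction="right",
            marker_idx=np.arange(3),
            distance_bp=np.array([0, 1_500_000, 1_600_000]),
            values=np.array([1.0, 0.04, 0.01]),
        )
        assert marker_h(curve, max_dist=1_000_000) is None


class TestRehh:
    def build_panel(self):
        """Core at index 2; allele-1 carriers stay homogeneous to the
        right, allele-0 carriers split; combined EHH decays into the
        0.03-0.05 band at the second flanking marker."""
        rng = np.random.default_rng(0)
        n = 40
        haps = np.zeros((n, 8), dtype=np.int8)
        haps[: n // 2, 2] = 1
        # markers 3..7: carriers of 0 get random alleles (fast decay),
        # carriers of 1 split only at marker 5
        haps[n // 2 :, 3:] = rng.integers(0, 2, size=(n // 2, 5))
        haps[: n // 4, 5] = 1
        return make_hapset(haps)

    def test_equal_ehh_gives_unit_rehh(self):
        haps = np.zeros((8, 3), dtype=np.int8)
        haps[:4, 1] = 1
        haps[[0, 1, 4, 5], 2] = 1  # both alleles split 2/2 at marker 2
        hs = make_hapset(haps)
        e1 = combined_ehh(hs, 1, "right")
        # force the band around the combined value at marker 2
        val = e1.values[1]
        out = rehh(hs, 1, "right", band=(val - 0.001, val + 0.001))
        assert out[0]["rehh"] == pytest.approx(1.0)
        assert out[1]["rehh"] == pytest.approx(1.0)
        assert out[0]["ln_rehh"] == pytest.approx(0.0)

    def test_rehh_is_ratio_of_per_allele_ehh(self):
        hs = self.build_panel()
        curve = combined_ehh(hs, 2, "right")
        in_band = [
            (k, v) for k, v in zip(curve.marker_idx[1:], curve.values[1:])
            if 0.03 <= v <= 0.05
        ]
        if not in_band:  # widen band to make the test well-posed
            band = (curve.values[2] - 0.01, curve.values[2] + 0.01)
        else:
            band = (0.03, 0.05)
        out = rehh(hs, 2, "right", band=band)
        assert set(out) == {0, 1}
        # allele 1 kept a longer homogeneous haplotype than allele 0
        assert out[1]["rehh"] > out[0]["rehh"]

    def test_swept_allele_shows_elevated_rehh(self):
        """Incomplete sweep (favored allele ~0.7): the favored allele's
        REHH at the selected site exceeds the unfavored allele's in most
        replicates."""
        wins = total = 0
        for seed in range(60):
            if total == 12:
                break
            cfg = SimConfig(
                n_anc=300, n_pop=500, g_burnin=80, g_split=250,
                seq_len_bp=4_000_000, n_snps=400, rec_rate=1e-7,
                sel_pos_bp=2_000_000, sel_coef=0.05, sel_init_freq=0.01,
                sel_stop_freq=0.7, max_retries=80, seed=seed,
            )
            try:
                a, _, truth = simulate_two_pop(cfg)
            except SweepLostError:
                continue
            j = int(np.nonzero(a.positions == truth.sel_pos_bp)[0][0])
            scores = {}
            for direction in ("left", "right"):
                for al, rec in rehh(a, j, direction).items():
                    scores.setdefault(al, []).append(rec["ln_rehh"])
            if len(scores) < 2:
                continue
            total += 1
            if max(scores[1]) > max(scores[0]):
                wins += 1
        assert total >= 8
        assert wins / total >= 0.8


class TestStandardize:
    def make_scan(self, freqs, ln_rehhs):
        return pd.DataFrame(
            {
                "snp": np.arange(len(freqs)),
                "id": [f"s{i}" for i in range(len(freqs))],
                "chrom": "1",
                "pos": np.arange(1, len(freqs) + 1) * 1000,
                "allele": 1,
                "direction": "right",
                "freq": freqs,
                "rehh": np.exp(ln_rehhs),
                "ln_rehh": ln_rehhs,
            }
        )

    def test_sample_sd_convention(self):
        out = standardize_lrh(self.make_scan([0.32, 0.33, 0.34], [1.0, 2.0, 3.0]))
        assert out["z"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_degenerate_bin_is_missing(self):
        out = standardize_lrh(self.make_scan([0.32, 0.33], [2.0, 2.0]))
        assert out["z"].isna().all()

    def test_singleton_bin_is_missing(self):
        out = standardize_lrh(self.make_scan([0.02], [1.0]))
        assert out["z"].isna().all()

    def test_bins_standardized_to_unit_moments(self):
        rng = np.random.default_rng(11)
        n = 4000
        scan = self.make_scan(rng.uniform(0, 1, n), rng.normal(0.0, 0.7, n))
        out = standardize_lrh(scan)
        for _, grp in out.groupby("freq_bin"):
            v = grp["z"].dropna()
            if len(v) < 2:
                continue
            assert abs(v.mean()) < 1e-10
            assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_frequency_binning_is_equal_width(self):
        scan = self.make_scan([0.01, 0.049, 0.05, 0.51, 0.99], np.zeros(5))
        out = standardize_lrh(scan)
        assert out["freq_bin"].tolist() == [0, 0, 1, 10, 19]
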