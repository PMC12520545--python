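"""Metric-correctness tests: PCC and OLS against closed-form oracles,
iRT normalization recovery of a known affine map, fragment matching
against a brute-force pairing oracle, and library-level comparisons
against analytic noise ceilings."""

import numpy as np
import pytest

from secproxy import chem, eval_metrics, proxy_transform, synth_gen
from secproxy.entities import Fragment, LibraryEntry, Peptide, SpectralLibrary
from secproxy.synth_gen import SynthConfig


def pcc_oracle(x, y):
    """Textbook Pearson formula via raw sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    return num / den


class TestSpectralPcc:
    def test_perfect_linear(self):
        assert eval_metrics.spectral_pcc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert eval_metrics.spectral_pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = [0.1, 0.9, 0.4, 1.0, 0.2]
        y = [0.2, 0.7, 0.5, 0.9, 0.1]
        assert eval_metrics.spectral_pcc(x, y) == pytest.approx(
            pcc_oracle(x, y), abs=1e-12
        )

    def test_zero_variance_invalid(self):
        assert eval_metrics.spectral_pcc([1, 1, 1], [1, 2, 3]) is None

    def test_too_few_pairs_invalid(self):
        assert eval_metrics.spectral_pcc([1, 2], [2, 1]) is None

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0, 1, 20)
        base = eval_metrics.spectral_pcc(x, y)
        assert eval_metrics.spectral_pcc(3.7 * x + 0.2, y) == pytest.approx(base, abs=1e-12)
        assert eval_metrics.spectral_pcc(x, 0.01 * y + 5) == pytest.approx(base, abs=1e-12)


def make_entry(seq="ACDEFK", charge=2, intensities=None):
    pep = Peptide(seq)
    n = len(seq)
    frags = []
    i = 0
    for t in "by":
        for k in range(1, n):
            inten = intensities[i] if intensities else 0.1 + ((k * 3 + (t == "y")) % 9) / 10
            frags.append(Fragment(t, k, 1, chem.fragment_mz(pep, t, k, 1), inten))
            i += 1
    return LibraryEntry(
        peptide=pep, charge=charge, precursor_mz=chem.precursor_mz(pep, charge),
        irt=10.0, fragments=tuple(frags), ion_mobility=1.0,
    )


class TestMatchFragments:
    def test_identical_entries(self):
        e = make_entry()
        x, y = eval_metrics.match_fragments(e, e)
        assert np.array_equal(x, y)
        assert x.size == len(e.fragments)

    def test_sec_twin_annotation_pairing_total(self):
        iodo = chem.get_modification("IodoAPB-CAM")
        pep = Peptide("ACDEFK", ((2, iodo),))
        frags = tuple(
            Fragment(t, k, 1, chem.fragment_mz(pep, t, k, 1), 0.5)
            for t in "by" for k in range(1, 6)
        )
        e = LibraryEntry(pep, 2, chem.precursor_mz(pep, 2), 5.0, frags)
        twin = proxy_transform.cys_to_sec(e)
        x, y = eval_metrics.match_fragments(e, twin)
        assert x.size == len(frags)  # pairing total despite m/z shifts
        assert np.all(x > 0) and np.all(y > 0)

    def test_mz_mode_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = make_entry(intensities=list(rng.uniform(0.1, 1, 10)))
            # jitter fragment m/z within/outside tolerance
            jitter = rng.normal(0, 8e-6, len(a.fragments))
            b_frags = tuple(
                Fragment("x", i, 1, f.mz * (1 + jitter[i]), rng.uniform(0.1, 1))
                for i, f in enumerate(a.fragments)
            )
            b = LibraryEntry(a.peptide, 2, a.precursor_mz, 5.0, b_frags)
            x, y = eval_metrics.match_fragments(a, b, tol_ppm=15, by_annotation=False,
                                                drop_unmatched=True)
            # oracle: all pairs within tolerance, greedy by ppm, one-to-one
            pairs = sorted(
                (abs(f.mz - g.mz) / f.mz * 1e6, i, j)
                for i, f in enumerate(a.fragments)
                for j, g in enumerate(b.fragments)
                if abs(f.mz - g.mz) / f.mz * 1e6 <= 15
            )
            ua, ub, expected = set(), set(), []
            for _, i, j in pairs:
                if i not in ua and j not in ub:
                    ua.add(i)
                    ub.add(j)
                    expected.append((a.fragments[i].intensity, b_frags[j].intensity))
            got = sorted(zip(x, y))
            assert got == sorted(expected)

    def test_zero_fill_default(self):
        a = make_entry()
        b = LibraryEntry(a.peptide, 2, a.precursor_mz, 5.0, a.fragments[:3])
        x, y = eval_metrics.match_fragments(a, b)
        assert x.size == len(a.fragments)
        assert np.sum(y == 0) == len(a.fragments) - 3


def ols_oracle(x, y):
    """Normal equations for simple linear regression."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yhat = X @ beta
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return beta[1], beta[0], 1 - ss_res / ss_tot


class TestRegress:
    def test_identity_line(self):
        x = np.arange(10.0)
        res = eval_metrics.regress(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.pvalue < 1e-10

    def test_textbook_five_points(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.1, 3.9, 6.2, 8.0, 9.8]
        res = eval_metrics.regress(x, y)
        slope, intercept, r2 = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_n_two_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            eval_metrics.regress([1, 2], [1, 2])

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant"):
            eval_metrics.regress([1, 1, 1], [1, 2, 3])

    def test_r2_bounds(self):
        rng = np.random.default_rng(1)
        res = eval_metrics.regress(rng.normal(size=30), rng.normal(size=30))
        assert 0 <= res.r2 <= 1


class TestNormalizeIrt:
    def test_self_reference_identity(self):
        run = [("A", 10.0), ("B", 50.0), ("C", 90.0)]
        out = eval_metrics.normalize_irt(run, reference=run)
        for (p, v), (_, w) in zip(out, run):
            assert v == pytest.approx(w, abs=1e-9)

    def test_recovers_known_affine_map(self):
        rng = np.random.default_rng(12)
        irt = rng.uniform(0, 120, 60)
        eps = 0.05
        rts = 0.5 * irt + 3 + rng.normal(0, eps, irt.size)
        run = [(f"p{i}", float(rt)) for i, rt in enumerate(rts)]
        ref = [(f"p{i}", float(v)) for i, v in enumerate(irt)]
        out = dict(eval_metrics.normalize_irt(run, reference=ref))
        fit = eval_metrics.regress(rts, [out[f"p{i}"] for i in range(60)])
        # the fitted map must be ~ rt -> 2 rt - 6, within 3 sigma of OLS error
        se_slope = 2 * eps / (np.std(rts) * np.sqrt(60))
        assert abs(fit.slope - 2.0) < 3 * se_slope
        assert abs(fit.intercept - (-6.0)) < 3 * se_slope * np.mean(rts) * 2

    def test_scaling_mode(self):
        out = eval_metrics.normalize_irt(
            [("p", 15.0)], gradient_actual=30.0, gradient_min=120.0
        )
        assert out == [("p", 60.0)]

    def test_too_few_anchors(self):
        with pytest.raises(ValueError, match="scaling mode"):
            eval_metrics.normalize_irt([("A", 1.0)], reference=[("A", 2.0)])


class TestCompareLibraries:
    def test_self_comparison_perfect(self, small_cys_library):
        _, lib, _ = small_cys_library
        report = eval_metrics.compare_libraries(lib, lib)
        assert report["median_pcc"] == pytest.approx(1.0, abs=1e-12)
        assert report["rt_regression"].r2 == pytest.approx(1.0, abs=1e-12)
        assert report["im_regression"].r2 == pytest.approx(1.0, abs=1e-12)
        assert report["n"] == len(lib)

    def test_noisy_copy_hits_analytic_ceiling(self):
        cfg = SynthConfig(n_peptides=300, seed=33, sigma_ms2=0.15)
        lib, truth = synth_gen.generate_cys_library(cfg)
        noiseless_cfg = SynthConfig(n_peptides=300, seed=33, sigma_rt=0,
                                    sigma_ccs=0, sigma_ms2=0)
        clean, _ = synth_gen.generate_cys_library(noiseless_cfg)
        report = eval_metrics.compare_libraries(clean, lib)
        ceiling = synth_gen.ms2_noise_ceiling(truth.ms2, cfg.sigma_ms2)
        assert report["median_pcc"] == pytest.approx(ceiling, abs=0.02)

    def test_median_pcc_symmetric(self, small_cys_library):
        cfg, lib, truth = small_cys_library
        sec, _ = synth_gen.generate_sec_holdout(cfg, lib, truth)
        fwd = eval_metrics.compare_libraries(lib, sec, proxy_pairing=True)
        # reverse direction: map keys the same way
        rev = eval_metrics.compare_libraries(sec, lib, proxy_pairing=True)
        assert fwd["median_pcc"] == pytest.approx(rev["median_pcc"], abs=1e-12)

    def test_zero_overlap_errors(self, small_cys_library):
        _, lib, _ = small_cys_library
        empty = SpectralLibrary(entries=[make_entry("WWDEFK")])
        with pytest.raises(ValueError, match="no precursors shared"):
            eval_metrics.compare_libraries(empty, lib)
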