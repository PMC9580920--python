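import numpy as np
import pytest

from rnadesc import fixtures as fx
from rnadesc.base_geometry import CylCoord
from rnadesc.dataset_report import (analyze_structure, fit_linear_through_origin,
                                    fit_pair_gaussians, fit_power_law, summarize)


class TestPowerLawFit:
    def test_exact_recovery_on_noiseless_flory_curve(self):
        L = np.arange(20, 501, 10, dtype=float)
        a, b = fit_power_law(list(zip(L, 6.7 * L ** 0.31)))
        assert a == pytest.approx(6.7, abs=1e-9)
        assert b == pytest.approx(0.31, abs=1e-12)

    def test_short_chain_restriction(self):
        L = np.arange(20, 501, 10, dtype=float)
        pts = [(l, (5.1 * l ** 0.37) if l < 100 else 123.0) for l in L]
        a, b = fit_power_law(pts, l_max=100.0)
        assert (a, b) == pytest.approx((5.1, 0.37), abs=1e-9)

    def test_constant_rg_gives_zero_exponent(self):
        a, b = fit_power_law([(10.0, 4.0), (100.0, 4.0), (400.0, 4.0)])
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(4.0, rel=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(10.0, -1.0), (20.0, 3.0)])
        with pytest.raises(ValueError):
            fit_power_law([(50.0, 3.0), (50.0, 3.5)])  # one distinct L

    def test_noise_recovery_within_two_sd(self):
        rng = np.random.default_rng(42)
        L = np.arange(20, 501, 5, dtype=float)
        rg = 6.7 * L ** 0.31 * np.exp(rng.normal(0, 0.05, size=L.size))
        a, b = fit_power_law(list(zip(L, rg)))
        # analytic sd of the slope in log-log space with sigma=0.05
        x = np.log(L)
        sd_b = 0.05 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(b - 0.31) < 2 * sd_b


class TestLinearThroughOrigin:
    @pytest.mark.parametrize("k", [0.48, 0.21])
    def test_exact_recovery(self, k):
        L = np.arange(10, 400, 7, dtype=float)
        assert fit_linear_through_origin(list(zip(L, k * L))) == pytest.approx(k, abs=1e-12)

    def test_single_point(self):
        assert fit_linear_through_origin([(100.0, 50.0)]) == pytest.approx(0.5)

    def test_needs_positive_length(self):
        with pytest.raises(ValueError):
            fit_linear_through_origin([])


class TestPairGaussians:
    def test_identical_records_have_zero_spread(self):
        recs = [(("A", "U", "cWW"), CylCoord(7.0, 0.0, 0.0))] * 5
        fit = fit_pair_gaussians(recs)[("A", "U", "cWW")]
        assert (fit.rho_mean, fit.theta_mean, fit.z_mean) == (7.0, 0.0, 0.0)
        assert (fit.rho_sd, fit.theta_sd, fit.z_sd) == (0.0, 0.0, 0.0)

    def test_circular_mean_wraps(self):
        recs = [(("A", "U", "cWW"), CylCoord(7.0, 350.0, 0.0)),
                (("A", "U", "cWW"), CylCoord(7.0, 10.0, 0.0))]
        fit = fit_pair_gaussians(recs)[("A", "U", "cWW")]
        assert fit.theta_mean == pytest.approx(0.0, abs=1e-9)

    def test_sampling_recovers_generator_mean(self):
        rng = np.random.default_rng(7)
        n = 10_000
        rhos = rng.normal(7.0, 0.3, size=n)
        recs = [(("G", "C", "cWW"), CylCoord(float(r), 0.0, 0.0)) for r in rhos]
        fit = fit_pair_gaussians(recs)[("G", "C", "cWW")]
        assert abs(fit.rho_mean - 7.0) < 3 * 0.3 / np.sqrt(n)

    def test_small_classes_reported_unfitted(self):
        recs = [(("A", "A", "tHS"), CylCoord(5.0, 90.0, 1.0))]
        fit = fit_pair_gaussians(recs)[("A", "A", "tHS")]
        assert fit.n == 1 and np.isnan(fit.rho_sd)


@pytest.fixture(scope="module")
def reports():
    specs = ["GCGCAU", "GGCAUCC", "GCAUGCGC"]
    sts, reps = [], []
    for s in specs:
        st, _ = fx.make_duplex(fx.HelixSpec(s))
        sts.append(st)
        reps.append(analyze_structure(st))
    return sts, reps


class TestSummarize:
    def test_row_per_structure_and_partition(self, reports):
        sts, reps = reports
        summ = summarize(reps, structures=sts)
        assert summ.n_structures == len(reps) == len(summ.table)
        assert abs(sum(summ.motifs.nucleotide_freq.values()) - 1.0) < 1e-12
        assert abs(sum(summ.motifs.pair_freq.values()) - 1.0) < 1e-12

    def test_permutation_invariance(self, reports):
        sts, reps = reports
        a = summarize(reps, structures=sts)
        b = summarize(list(reversed(reps)), structures=list(reversed(sts)))
        assert a.table.equals(b.table)
        assert a.nbp_slope == b.nbp_slope
        assert a.motifs.stem_lengths == b.motifs.stem_lengths

    def test_single_structure_skips_fits(self, reports):
        sts, reps = reports
        summ = summarize(reps[:1], structures=sts[:1])
        assert summ.power_law is None           # one distinct length only
        assert summ.nbp_slope is not None       # slope works from one point

    def test_duplicated_structure_changes_counts_not_frequencies(self, reports):
        sts, reps = reports
        one = summarize(reps[:1], structures=sts[:1])
        two = summarize([reps[0], reps[0]], structures=[sts[0], sts[0]])
        assert two.motifs.pair_freq == one.motifs.pair_freq

    def test_fraction_below_asphericity_threshold(self):
        class FakeShape:
            def __init__(self, d):
                self.rg, self.eigenvalues = 5.0, (9.0, 8.0, 8.0)
                self.asphericity, self.shape, self.n_atoms = d, 0.0, 10

        from rnadesc.dataset_report import StructureReport
        from rnadesc.motif_decomposition import decompose
        reps = [StructureReport(id=f"s{k}", length=10, shape=FakeShape(d),
                                pairs=[], stacks=[],
                                secondary=decompose(10, []))
                for k, d in enumerate([0.1, 0.3])]
        summ = summarize(reps)
        assert summ.fraction_delta_below[0.2] == 0.5
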