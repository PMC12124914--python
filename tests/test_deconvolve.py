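import math

import numpy as np
import pytest
from scipy import integrate

from cfdeconv.deconvolve import (
    UNKNOWN,
    FragmentEvidence,
    assign_fragment,
    build_evidence,
    cf_deconvolve,
    estimate_tumor_burden,
    fragment_loglik,
    plot_fraction_pie,
    read_fractions,
    write_fractions,
    write_tumor_burden,
)
from cfdeconv.markers import BetaParams
from cfdeconv.simulate import SimulationConfig, simulate_fragments


def quadrature_loglik(n, k, alpha, beta):
    """Independent oracle: numerically integrate p^k (1-p)^(n-k) Beta(p; a, b)."""
    from scipy.special import betaln

    lognorm = betaln(alpha, beta)
    aa, bb = alpha + k - 1.0, beta + n - k - 1.0

    def integrand(p):
        if p <= 0.0 or p >= 1.0:
            return 0.0
        return math.exp(aa * math.log(p) + bb * math.log(1.0 - p) - lognorm)

    value, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=0, epsrel=1e-11, limit=100)
    return math.log(value)


def _evidence(llt, lln, marker_id="m", n=4, k=2):
    return FragmentEvidence(marker_id, n, k, {"tumor": llt, "normal": lln})


class TestFragmentLoglik:
    def test_zero_cpgs_is_zero(self):
        assert fragment_loglik(0, 0, BetaParams(3, 7)) == 0.0

    def test_single_cpg_uniform_prior(self):
        assert fragment_loglik(1, 1, BetaParams(1, 1)) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_fully_methylated_against_quadrature(self):
        # closed form B(6,8)/B(2,8) = 1/143
        got = fragment_loglik(4, 4, BetaParams(2, 8))
        assert got == pytest.approx(math.log(1 / 143), abs=1e-10)
        assert got == pytest.approx(quadrature_loglik(4, 4, 2, 8), abs=1e-8)

    @pytest.mark.parametrize("alpha", [0.5, 2, 20])
    @pytest.mark.parametrize("beta", [0.5, 8])
    def test_quadrature_spot_lattice(self, alpha, beta):
        for n in (1, 5, 12):
            for k in range(n + 1):
                assert fragment_loglik(n, k, BetaParams(alpha, beta)) == pytest.approx(
                    quadrature_loglik(n, k, alpha, beta), abs=1e-8
                )

    def test_always_nonpositive(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.1, 50, 2)
            assert fragment_loglik(n, k, BetaParams(a, b)) <= 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError, match="k_meth"):
            fragment_loglik(3, 4, BetaParams(1, 1))


class TestEstimateTumorBurden:
    def test_flat_profile_ties_to_zero(self):
        evidence = [_evidence(-1.0, -1.0) for _ in range(10)]
        result = estimate_tumor_burden(evidence, grid_step=0.01)
        assert result.theta == 0.0
        lls = [ll for _, ll in result.loglik_profile]
        assert max(lls) - min(lls) < 1e-9

    def test_boundary_forcing_to_one(self):
        evidence = [_evidence(-1.0, -math.inf) for _ in range(5)]
        result = estimate_tumor_burden(evidence, grid_step=0.01)
        assert result.theta == 1.0

    def test_profile_shape_and_theta_at_max(self):
        evidence = [_evidence(-0.5, -2.0), _evidence(-3.0, -0.2)]
        result = estimate_tumor_burden(evidence, grid_step=0.05)
        grid = [t for t, _ in result.loglik_profile]
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert len(result.loglik_profile) == 21
        best = max(ll for _, ll in result.loglik_profile)
        at_theta = dict(result.loglik_profile)[result.theta]
        assert at_theta == pytest.approx(best, abs=1e-12)

    def test_recovery_at_theta_02(self):
        config = SimulationConfig.uniform_markers(
            {"tumor": BetaParams(8, 2), "normal": BetaParams(2, 8)},
            {"tumor": 0.2, "normal": 0.8},
            n_markers=10,
            n_fragments=5000,
            seed=42,
        )
        sim = simulate_fragments(config)
        evidence = build_evidence(sim.fragment_list(), sim.markers)
        result = estimate_tumor_burden(evidence)
        assert result.theta == pytest.approx(0.2, abs=0.03)
        # cross-check against a brute-force fine-grid maximization
        llt = np.array([e.per_class_loglik["tumor"] for e in evidence])
        lln = np.array([e.per_class_loglik["normal"] for e in evidence])
        fine = np.linspace(0.15, 0.25, 2001)
        with np.errstate(divide="ignore"):
            obj = [
                np.logaddexp(np.log(t) + llt, np.log(1 - t) + lln).sum() for t in fine
            ]
        assert result.theta == pytest.approx(fine[int(np.argmax(obj))], abs=1e-3)

    def test_monotone_in_tumorlike_fragments(self):
        base = [_evidence(-1.0, -0.5) for _ in range(50)] + [
            _evidence(-0.3, -1.5) for _ in range(10)
        ]
        theta0 = estimate_tumor_burden(base, grid_step=0.001).theta
        extended = base + [_evidence(-0.2, -2.0) for _ in range(5)]
        theta1 = estimate_tumor_burden(extended, grid_step=0.001).theta
        assert theta1 >= theta0

    def test_trimming_counts_and_excludes(self):
        quiet = [_evidence(-1.1, -1.0) for _ in range(90)]
        loud = [_evidence(-0.1, -40.0) for _ in range(10)]
        result = estimate_tumor_burden(quiet + loud, grid_step=0.01, trim_fraction=0.1)
        assert result.n_fragments_trimmed == 10
        assert result.n_fragments_used == 90
        no_trim = estimate_tumor_burden(quiet + loud, grid_step=0.01)
        assert result.theta < no_trim.theta  # the loud tumor outliers are gone

    def test_refine_improves_resolution(self):
        evidence = [_evidence(-0.5, -2.0) for _ in range(30)] + [
            _evidence(-2.0, -0.5) for _ in range(70)
        ]
        coarse = estimate_tumor_burden(evidence, grid_step=0.1)
        refined = estimate_tumor_burden(evidence, grid_step=0.1, refine=True)
        best = dict(coarse.loglik_profile)[coarse.theta]
        llt = np.array([e.per_class_loglik["tumor"] for e in evidence])
        lln = np.array([e.per_class_loglik["normal"] for e in evidence])

        def obj(t):
            return float(np.logaddexp(math.log(t) + llt, math.log(1 - t) + lln).sum())

        assert obj(refined.theta) >= best - 1e-12

    def test_empty_evidence_error(self):
        with pytest.raises(ValueError, match="no fragment evidence"):
            estimate_tumor_burden([])

    def test_bad_grid_step_error(self):
        with pytest.raises(ValueError, match="grid_step"):
            estimate_tumor_burden([_evidence(-1, -1)], grid_step=0.5)

    def test_both_zero_likelihood_error(self):
        with pytest.raises(ValueError, match="zero likelihood"):
            estimate_tumor_burden([_evidence(-math.inf, -math.inf)])

    def test_missing_class_error(self):
        evidence = [FragmentEvidence("m", 2, 1, {"a": -1.0, "b": -2.0})]
        with pytest.raises(ValueError, match="lacks class"):
            estimate_tumor_burden(evidence)


class TestAssignFragment:
    def _ev(self, **lls):
        return FragmentEvidence("m", 4, 2, {c: math.log(v) if v > 0 else -math.inf for c, v in lls.items()})

    def test_below_threshold_is_unknown(self):
        assert assign_fragment(self._ev(a=0.4, b=0.3), 2.0) == UNKNOWN

    def test_above_threshold_assigns_top(self):
        assert assign_fragment(self._ev(a=0.9, b=0.3, c=0.1), 2.0) == "a"

    def test_exact_tie_is_unknown(self):
        assert assign_fragment(self._ev(a=0.5, b=0.5), 1.0) == UNKNOWN

    def test_threshold_boundary_inclusive(self):
        assert assign_fragment(self._ev(a=0.6, b=0.3), 2.0) == "a"

    def test_zero_runner_up(self):
        assert assign_fragment(self._ev(a=0.5, b=0.0), 100.0) == "a"

    def test_fewer_than_two_classes_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            assign_fragment(FragmentEvidence("m", 1, 0, {"a": -1.0}))

    def test_threshold_below_one_error(self):
        with pytest.raises(ValueError, match=">= 1"):
            assign_fragment(self._ev(a=0.5, b=0.2), 0.5)


class TestCfDeconvolve:
    def _evidence_set(self):
        rng = np.random.default_rng(9)
        evidence = []
        for cls, count in [("liver", 60), ("lung", 30)]:
            for _ in range(count):
                lls = {"liver": -5.0, "lung": -5.0}
                lls[cls] = -0.5
                evidence.append(FragmentEvidence("m", 3, 1, lls))
        for _ in range(10):
            evidence.append(FragmentEvidence("m", 3, 1, {"liver": -1.0, "lung": -1.0}))
        rng.shuffle(evidence)
        return evidence

    def test_normalization(self):
        result = cf_deconvolve(self._evidence_set(), 2.0)
        assert result.fractions == {
            "liver": pytest.approx(0.6),
            "lung": pytest.approx(0.3),
            UNKNOWN: pytest.approx(0.1),
        }
        assert result.class_counts == {"liver": 60, "lung": 30}
        assert result.unknown_count == 10

    def test_all_ambiguous(self):
        evidence = [FragmentEvidence("m", 2, 1, {"a": -1.0, "b": -1.0}) for _ in range(5)]
        result = cf_deconvolve(evidence)
        assert result.fractions[UNKNOWN] == 1.0

    def test_two_class_tumor_split_matches_direct_comparison(self):
        tumor, normal = BetaParams(8, 2), BetaParams(2, 8)
        evidence = []
        for n, k in [(6, 6), (6, 0), (5, 5), (8, 1), (4, 4)]:
            evidence.append(
                FragmentEvidence(
                    "m",
                    n,
                    k,
                    {
                        "tumor": fragment_loglik(n, k, tumor),
                        "normal": fragment_loglik(n, k, normal),
                    },
                )
            )
        result = cf_deconvolve(evidence, 2.0)
        # oracle: direct per-fragment likelihood comparison
        expected_tumor = sum(
            1
            for e in evidence
            if e.per_class_loglik["tumor"] - e.per_class_loglik["normal"] >= math.log(2)
        )
        assert result.class_counts["tumor"] == expected_tumor

    def test_fractions_sum_to_one(self, rng):
        for _ in range(20):
            evidence = [
                FragmentEvidence(
                    "m", 3, 1, {c: float(-rng.uniform(0.1, 9)) for c in ("a", "b", "c")}
                )
                for _ in range(int(rng.integers(1, 50)))
            ]
            result = cf_deconvolve(evidence, float(rng.uniform(1, 5)))
            assert sum(result.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_permuting_classes_permutes_fractions(self):
        evidence = self._evidence_set()
        permuted = [
            FragmentEvidence(
                e.marker_id,
                e.n_cpg,
                e.k_meth,
                {c: e.per_class_loglik[c] for c in reversed(e.classes)},
            )
            for e in evidence
        ]
        a = cf_deconvolve(evidence, 2.0)
        b = cf_deconvolve(permuted, 2.0)
        assert a.fractions == b.fractions

    def test_unknown_monotone_in_threshold(self, rng):
        evidence = [
            FragmentEvidence("m", 3, 1, {c: float(-rng.uniform(0.1, 6)) for c in ("a", "b", "c")})
            for _ in range(300)
        ]
        unknowns = [
            cf_deconvolve(evidence, t).fractions[UNKNOWN] for t in (1, 1.5, 2, 5, 10, 100)
        ]
        assert unknowns == sorted(unknowns)

    def test_empty_evidence_actionable_error(self):
        with pytest.raises(ValueError, match="marker regions"):
            cf_deconvolve([])

    def test_inconsistent_classes_error(self):
        evidence = [
            FragmentEvidence("m", 2, 1, {"a": -1.0, "b": -2.0}),
            FragmentEvidence("m", 2, 1, {"a": -1.0, "c": -2.0}),
        ]
        with pytest.raises(ValueError, match="inconsistent class sets"):
            cf_deconvolve(evidence)


class TestReportsAndPlot:
    def test_fraction_table_round_trip(self, tmp_path):
        result = cf_deconvolve(
            [FragmentEvidence("m", 3, 3, {"a": -0.1, "b": -5.0}) for _ in range(4)]
        )
        path = tmp_path / "fractions.tsv"
        write_fractions(result, path)
        assert read_fractions(path) == {"a": 1.0, "b": 0.0, UNKNOWN: 0.0}

    def test_tumor_burden_report(self, tmp_path):
        result = estimate_tumor_burden([_evidence(-0.5, -2.0)], grid_step=0.1)
        path = tmp_path / "burden.tsv"
        write_tumor_burden(result, path)
        line = path.read_text().splitlines()[1].split("\t")
        assert float(line[0]) == result.theta
        assert int(line[1]) == 1

    def test_single_wedge(self, tmp_path):
        path = tmp_path / "pie.png"
        plot_fraction_pie({"A": 1.0}, path)
        assert path.stat().st_size > 0

    def test_two_equal_wedges(self, tmp_path):
        path = tmp_path / "pie.svg"
        plot_fraction_pie({"A": 0.5, "B": 0.5}, path)
        text = path.read_text()
        assert "50.0%" in text

    def test_bad_sum_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="sum to 1"):
            plot_fraction_pie({"A": 0.5, "B": 0.4}, tmp_path / "pie.png")

    def test_negative_fraction_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="non-negative"):
            plot_fraction_pie({"A": 1.5, "B": -0.5}, tmp_path / "pie.png")
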