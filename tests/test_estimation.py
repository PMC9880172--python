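"""Empirical-Bayes MAP, Laplace population fit, covariate search,
bootstrap and pcVPC — all on model-simulated data at desk scale."""

import numpy as np
import pytest

from toripk.estimation import (
    CovariateTerm,
    FitResult,
    ModelSpec,
    PKDataset,
    SubjectData,
    bootstrap_ci,
    empirical_bayes,
    laplace_fit,
    pcvpc,
    pcvpc_containment,
    scm_search,
)
from toripk.model_core import (
    CovariateProfile,
    RandomEffectsSpec,
    individual_parameters,
)
from toripk.simulate import DoseEvent, solve_concentration, solve_concentration_batch

from conftest import RICH_EVENTS, RICH_TIMES, TRUTH, make_rich_dataset

SINGLE_EVENTS = [DoseEvent(0.0, 240.0, 1.0)]
SINGLE_TIMES = np.array([1.0, 24.0, 168.0, 336.0, 672.0, 1008.0])


def _noise_free_subject(eta, theta_obj):
    ind = individual_parameters(theta_obj, CovariateProfile(), eta)
    prof = solve_concentration(ind, RICH_EVENTS, RICH_TIMES)
    return SubjectData(
        subject_id=1, events=RICH_EVENTS, obs_times=RICH_TIMES,
        dv=prof.concentrations,
    )


def _single_dose_dataset(
    n, seed, cl_fn=None, sigma=0.19, re=None, profiles=None
):
    """Constant-CL single-dose dataset; cl_fn maps a profile to CL."""
    rng = np.random.default_rng(seed)
    re = re or RandomEffectsSpec.from_cv(1e-4, 0.31, 0.27, 0.39, sigma)
    profiles = profiles or [CovariateProfile() for _ in range(n)]
    etas = rng.multivariate_normal(np.zeros(3), re.omega, size=n, method="eigh")
    cl = np.array(
        [
            (cl_fn(p) if cl_fn else 14.9) * np.exp(e[1])
            for p, e in zip(profiles, etas)
        ]
    )
    v1 = 3710.0 * np.exp(etas[:, 2])
    conc = solve_concentration_batch(
        cl, v1, 36.5, 796.0, np.zeros(n), 1580.0, 1.32,
        SINGLE_EVENTS, SINGLE_TIMES,
    )
    subs = [
        SubjectData(
            subject_id=i, events=SINGLE_EVENTS, obs_times=SINGLE_TIMES,
            dv=np.maximum(conc[i] * (1 + rng.normal(0, sigma, SINGLE_TIMES.size)), 1e-3),
            profile=profiles[i],
        )
        for i in range(n)
    ]
    return PKDataset(subs)


CONST_INIT = {
    "cl_tv": 12.0, "v1_tv": 3200.0, "q_tv": 36.5, "v2_tv": 796.0,
    "emax_tv": 0.0, "t50": 1580.0, "gamma": 1.32, "sigma_prop": 0.19,
}
CONST_SPEC = ModelSpec(time_varying=False)
NULL_RE = RandomEffectsSpec.from_cv(1e-4, 0.31, 0.27, 0.39, 0.19)


class TestEmpiricalBayes:
    def test_noise_free_recovery(self, theta, re_spec):
        """MAP recovers the generating etas to 1e-2 on dense noise-free
        data when the residual SD reflects the (absent) noise."""
        eta_true = np.array([0.1, -0.2, 0.15])
        sub = _noise_free_subject(eta_true, theta)
        params = dict(TRUTH, sigma_prop=0.02)
        eta_hat, ind = empirical_bayes(params, re_spec, sub)
        assert np.max(np.abs(eta_hat - eta_true)) < 1e-2
        assert ind["cl_base"] == pytest.approx(14.9 * np.exp(eta_hat[1]), rel=1e-9)

    def test_first_order_optimality(self, theta, re_spec):
        """The returned mode is a local minimum of the joint neg-log
        posterior along each eta axis."""
        sub = _noise_free_subject(np.array([0.05, 0.1, -0.1]), theta)
        params = dict(TRUTH, sigma_prop=0.05)
        eta_hat, _ = empirical_bayes(params, re_spec, sub)

        p_mat = np.linalg.inv(re_spec.omega)
        sigma = 0.05

        def g(eta):
            ind = individual_parameters(theta, CovariateProfile(), eta)
            f = solve_concentration(ind, RICH_EVENTS, RICH_TIMES, rtol=1e-10)
            f = np.maximum(f.concentrations, 1e-6)
            e = sub.dv - f
            return 0.5 * float(
                np.sum((e / (sigma * f)) ** 2 + 2 * np.log(f))
                + eta @ p_mat @ eta
            )

        g0 = g(eta_hat)
        for k in range(3):
            for d in (1e-3, -1e-3):
                eta = eta_hat.copy()
                eta[k] += d
                assert g(eta) >= g0 - 1e-6

    def test_matches_grid_search_with_weak_prior(self, theta):
        """With a diffuse prior the MAP is the ML solution; a brute-force
        lattice search on the rich design (where all three etas are
        identified) agrees to within the grid resolution."""
        wide = RandomEffectsSpec.from_cv(5.0, 5.0, 5.0, 0.0, 0.15)
        rng = np.random.default_rng(3)
        ind = individual_parameters(theta, CovariateProfile(), (0.0, 0.0, 0.0))
        prof = solve_concentration(ind, RICH_EVENTS, RICH_TIMES)
        dv = np.maximum(prof.concentrations * (1 + rng.normal(0, 0.15, RICH_TIMES.size)), 1e-3)
        sub = SubjectData(1, RICH_EVENTS, RICH_TIMES, dv)
        params = dict(TRUTH, sigma_prop=0.15)
        eta_hat, _ = empirical_bayes(params, wide, sub)

        # brute force over a 9^3 lattice around zero
        grid = np.linspace(-0.4, 0.4, 9)
        best, best_val = None, np.inf
        p_mat = np.linalg.inv(wide.omega)
        for a in grid:
            for b in grid:
                for c in grid:
                    eta = np.array([a, b, c])
                    ind_g = individual_parameters(theta, CovariateProfile(), eta)
                    f = solve_concentration_batch(
                        np.array([ind_g.cl_base]), ind_g.v1, ind_g.q, ind_g.v2,
                        ind_g.emax_i, ind_g.t50, ind_g.gamma,
                        RICH_EVENTS, RICH_TIMES,
                    )[0]
                    f = np.maximum(f, 1e-6)
                    e = dv - f
                    val = 0.5 * (
                        np.sum((e / (0.15 * f)) ** 2 + 2 * np.log(f))
                        + eta @ p_mat @ eta
                    )
                    if val < best_val:
                        best, best_val = eta, val
        step = grid[1] - grid[0]
        assert np.max(np.abs(eta_hat - best)) <= step

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            SubjectData(1, SINGLE_EVENTS, np.array([]), np.array([]))


class TestLaplaceFit:
    def test_ofv_invariant_to_subject_order(self, re_spec):
        ds = make_rich_dataset(24, seed=5, re_spec=re_spec)
        shuffled = PKDataset(list(reversed(ds.subjects)))
        a = laplace_fit(ds, TRUTH, re_spec, [])
        b = laplace_fit(shuffled, TRUTH, re_spec, [])
        assert a.ofv == pytest.approx(b.ofv, abs=1e-3)

    def test_time_varying_beats_constant_on_tv_data(
        self, recovery_dataset, recovery_fit, re_spec
    ):
        """Fitting constant CL to time-varying data costs a large OFV
        penalty (the published refit reported ~1,200 units)."""
        const = laplace_fit(
            recovery_dataset, CONST_INIT, re_spec, ["cl_tv", "v1_tv"],
            spec=CONST_SPEC, maxiter=200,
        )
        assert recovery_fit.ofv < const.ofv - 100.0

    def test_no_false_time_dependence_on_constant_data(self):
        """LRT null calibration: on constant-CL data, adding the Emax term
        (1 df, t50 fixed) gains less than 3.84 in most replicates."""
        ok = 0
        reps = 6
        for rep in range(reps):
            ds = _single_dose_dataset(30, seed=100 + rep)
            const = laplace_fit(
                ds, CONST_INIT, NULL_RE, ["cl_tv", "v1_tv"],
                spec=CONST_SPEC, maxiter=150,
            )
            tv_init = dict(CONST_INIT, emax_tv=-0.05)
            tv = laplace_fit(
                ds, tv_init, NULL_RE, ["cl_tv", "v1_tv", "emax_tv"], maxiter=200,
            )
            delta = const.ofv - tv.ofv
            if delta <= 3.84:
                ok += 1
        assert ok >= int(0.8 * reps)

    def test_estimate_mask_limit(self, re_spec):
        ds = make_rich_dataset(4, seed=2, re_spec=re_spec)
        with pytest.raises(ValueError, match="at most 8"):
            laplace_fit(ds, TRUTH, re_spec, [f"p{i}" for i in range(9)])


class TestSCM:
    def test_threshold_logic_with_stubbed_fits(self, re_spec):
        """Forward addition needs dOFV >= 6.63; a 5-unit gain is refused."""
        ds = make_rich_dataset(4, seed=3, re_spec=re_spec)
        cand = CovariateTerm("cl", "weight", "power", ref=64.0)
        strong = CovariateTerm("cl", "ldh", "power", ref=199.0)

        ofvs = {(): 1000.0, ("beta_cl_weight",): 995.0,
                ("beta_cl_ldh",): 980.0,
                ("beta_cl_ldh", "beta_cl_weight"): 975.0}

        def stub_fit(dataset, init, re, estimate, spec=ModelSpec(), **kw):
            key = tuple(sorted(t.name for t in spec.covariate_terms))
            return FitResult(estimates={}, ofv=ofvs[key], converged=True)

        res = scm_search(
            ds, TRUTH, re_spec, ["cl_tv"], [cand, strong], fit_fn=stub_fit
        )
        # ldh enters (dOFV 20); weight then offers only 5 and is refused;
        # backward keeps ldh (removal would cost 20 > 10.83)
        assert [t.name for t in res["selected"]] == ["beta_cl_ldh"]
        steps = [(s["step"], s["term"], s["accepted"]) for s in res["log"]]
        assert ("forward", "beta_cl_ldh", True) in steps
        assert ("forward", "beta_cl_weight", False) in steps
        assert ("backward", "beta_cl_ldh", False) in steps

    def test_detects_strong_weight_effect(self):
        """CL ~ (WT/64)^0.75 survives forward addition and the stringent
        backward threshold.  n=250 keeps the LRT noncentrality (~40) far
        enough above 10.83 that failures are ~1% per replicate."""
        rng = np.random.default_rng(21)
        hits = 0
        reps = 2
        cands = [
            CovariateTerm("cl", "weight", "power", ref=64.0),
            CovariateTerm("cl", "albumin", "power", ref=43.7),
        ]
        for rep in range(reps):
            profiles = [
                CovariateProfile(
                    weight=float(np.exp(rng.normal(np.log(64), 0.25))),
                    albumin=float(np.exp(rng.normal(np.log(43.7), 0.15))),
                )
                for _ in range(250)
            ]
            ds = _single_dose_dataset(
                250, seed=300 + rep,
                cl_fn=lambda p: 14.9 * (p.weight / 64.0) ** 0.75,
                profiles=profiles,
            )
            res = scm_search(
                ds, CONST_INIT, NULL_RE, ["cl_tv", "v1_tv"], cands,
                spec=CONST_SPEC, maxiter=120,
            )
            if any(t.covariate == "weight" for t in res["selected"]):
                hits += 1
        assert hits == reps

    def test_null_data_mostly_empty_selection(self):
        rng = np.random.default_rng(31)
        empty = 0
        reps = 3
        cands = [
            CovariateTerm("cl", "weight", "power", ref=64.0),
            CovariateTerm("cl", "albumin", "power", ref=43.7),
        ]
        for rep in range(reps):
            profiles = [
                CovariateProfile(
                    weight=float(np.exp(rng.normal(np.log(64), 0.22))),
                    albumin=float(np.exp(rng.normal(np.log(43.7), 0.15))),
                )
                for _ in range(80)
            ]
            ds = _single_dose_dataset(80, seed=400 + rep, profiles=profiles)
            res = scm_search(
                ds, CONST_INIT, NULL_RE, ["cl_tv", "v1_tv"], cands,
                spec=CONST_SPEC, maxiter=120,
            )
            if not res["selected"]:
                empty += 1
        assert empty >= reps - 1


class TestBootstrap:
    def test_cloned_subjects_degenerate_and_reproducible(self):
        """Resampling identical subjects gives near-zero-width CIs, and a
        fixed seed reproduces the table exactly."""
        base = _single_dose_dataset(1, seed=50)
        clones = PKDataset(
            [
                SubjectData(i, base.subjects[0].events,
                            base.subjects[0].obs_times, base.subjects[0].dv)
                for i in range(15)
            ]
        )
        with pytest.warns(UserWarning, match="n_reps"):
            res1 = bootstrap_ci(
                clones, CONST_INIT, NULL_RE, ["cl_tv", "v1_tv"],
                n_reps=5, seed=9, spec=CONST_SPEC, maxiter=120,
            )
            res2 = bootstrap_ci(
                clones, CONST_INIT, NULL_RE, ["cl_tv", "v1_tv"],
                n_reps=5, seed=9, spec=CONST_SPEC, maxiter=120,
            )
        t1, t2 = res1["table"], res2["table"]
        assert res1["n_success"] == 5
        width = (t1["ci_high"] - t1["ci_low"]) / t1["median"]
        assert (width < 5e-3).all()
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-12)


class TestPcVPC:
    def test_identity_correction_without_iiv(self, theta):
        """All subjects identical and one time per bin: the correction is
        the identity, so observed stats equal the raw-DV stats."""
        tiny = RandomEffectsSpec.from_cv(1e-6, 1e-6, 1e-6, 0.0, 0.10)
        ds = _single_dose_dataset(40, seed=60, sigma=0.10, re=tiny)
        table = pcvpc(
            ds, TRUTH, tiny, n_sims=40, seed=1, n_bins=SINGLE_TIMES.size
        )
        dv = np.vstack([s.dv for s in ds.subjects])
        tad = SINGLE_TIMES  # single dose at t=0
        for _, row in table.iterrows():
            mask = (tad > row["tad_low"]) & (tad <= row["tad_high"]) | (
                np.isclose(tad, row["tad_low"]) & (row["bin"] == 0)
            )
            col = dv[:, mask].ravel()
            assert row["obs_p50"] == pytest.approx(np.percentile(col, 50), rel=1e-9)

    def test_self_consistency_three_seeds(self, re_spec):
        """Model-simulated data are contained in their own simulated PIs
        (>=85% of bin x percentile cells, pooled over three seeds)."""
        inside = total = 0
        for seed in (1, 2, 3):
            ds = _single_dose_dataset(40, seed=70 + seed, re=re_spec)
            table = pcvpc(ds, TRUTH, re_spec, n_sims=100, seed=seed, n_bins=6)
            cells = 3 * len(table)
            inside += pcvpc_containment(table) * cells
            total += cells
        assert inside / total >= 0.85

    def test_misspecified_clearance_detected(self, re_spec):
        """Doubling CL in the simulation model pushes at least half of the
        median cells outside their PIs."""
        ds = _single_dose_dataset(40, seed=80, re=re_spec)
        bad = dict(TRUTH, cl_tv=2 * 14.9)
        table = pcvpc(ds, bad, re_spec, n_sims=100, seed=4, n_bins=6)
        outside = (
            (table["obs_p50"] < table["sim_p50_lo"])
            | (table["obs_p50"] > table["sim_p50_hi"])
        )
        assert outside.mean() >= 0.5

    def test_sparse_bins_merged(self, re_spec):
        ds = _single_dose_dataset(3, seed=90, re=re_spec)
        # 3 subjects x 6 times: 10 requested bins must merge to keep >=5 obs
        table = pcvpc(ds, TRUTH, re_spec, n_sims=20, seed=5, n_bins=10)
        assert (table["n_obs"] >= 5).all()
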