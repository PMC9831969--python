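import numpy as np
import pytest
from scipy.special import expit

import deerscr
from deerscr import scr_model as scr
from deerscr.encounters import DetectionRecord, build_encounter_array
from deerscr.landscape import StateSpace, TrapArray

from oracles import oracle_neg_log_likelihood


# ---------------------------------------------------------------------------
# helpers

def one_pixel_setup():
    space = StateSpace(x=np.array([0.0]), y=np.array([0.0]), resolution=120.0)
    traps = TrapArray(ids=np.array(["t1"]), x=np.array([0.0]), y=np.array([0.0]))
    enc = build_encounter_array(
        [DetectionRecord("i1", "F", "t1", 1, "s1")], traps, {"s1": 1})
    return space, traps, enc


def random_toy(seed):
    """Random small instance (<=16 pixels, <=4 traps, <=3 occasions, 2
    sessions, 2 sexes) with data simulated forward at random parameters."""
    rng = np.random.default_rng(seed)
    npx = rng.integers(2, 5)  # grid side 2..4 -> 4..16 pixels
    res = 100.0
    gx, gy = np.meshgrid(np.arange(npx) * res, np.arange(npx) * res)
    space = StateSpace(x=gx.ravel().astype(float), y=gy.ravel().astype(float),
                       resolution=res)
    n_traps = int(rng.integers(2, 5))
    traps = TrapArray(
        ids=np.array([f"t{j}" for j in range(n_traps)]),
        x=rng.uniform(0, npx * res, n_traps), y=rng.uniform(0, npx * res, n_traps))
    occasions = {"A": int(rng.integers(1, 3)), "B": int(rng.integers(2, 4))}
    params = {
        "D.(Intercept)": rng.normal(-0.5, 0.5),
        "D.session[B]": rng.normal(0, 0.5),
        "p0.(Intercept)": rng.normal(-0.5, 0.5),
        "p0.session[B]": rng.normal(0, 0.3),
        "p0.occ[2]": rng.normal(0, 0.3),
        "p0.occ[3]": rng.normal(0, 0.3),
        "p0.sex[M]": rng.normal(0, 0.3),
        "sigma.(Intercept)": np.log(rng.uniform(80, 250)),
        "sigma.sex[M]": rng.normal(0, 0.2),
        "psi.(Intercept)": rng.normal(0, 0.5),
    }
    spec = scr.ModelSpec(density="~session", detection="~session+occ+sex",
                         sigma="~sex")
    # forward-simulate detections at these parameters
    records = []
    psi_f = expit(params["psi.(Intercept)"])
    for g, K in occasions.items():
        mu = np.exp(params["D.(Intercept)"] + (params["D.session[B]"] if g == "B" else 0))
        N = rng.poisson(mu * space.n_pixels)
        for i in range(N):
            s = rng.integers(space.n_pixels)
            sex = "F" if rng.random() < psi_f else "M"
            sig = np.exp(params["sigma.(Intercept)"]
                         + (params["sigma.sex[M]"] if sex == "M" else 0))
            for j in range(n_traps):
                d2 = (space.x[s] - traps.x[j]) ** 2 + (space.y[s] - traps.y[j]) ** 2
                for k in range(1, K + 1):
                    eta = (params["p0.(Intercept)"]
                           + (params["p0.session[B]"] if g == "B" else 0)
                           + params.get(f"p0.occ[{k}]", 0) * (k > 1)
                           + (params["p0.sex[M]"] if sex == "M" else 0))
                    p = expit(eta) * np.exp(-d2 / (2 * sig ** 2))
                    if rng.random() < p:
                        records.append(DetectionRecord(f"{g}i{i}", sex, f"t{j}", k, g))
    if {r.session for r in records} != {"A", "B"}:
        return None  # both sessions must be observed so contrasts identify
    enc = build_encounter_array(records, traps, occasions)
    return space, traps, enc, spec, params


def params_vector(nll, params):
    return np.array([params[name] for name in nll.names])


def make_oracle_fns(params):
    def mu_fn(g, s):
        return np.exp(params["D.(Intercept)"] + (params["D.session[B]"] if g == "B" else 0))

    def p0_fn(g, sex, j, k):
        eta = params["p0.(Intercept)"]
        if g == "B":
            eta += params["p0.session[B]"]
        if k == 1:
            eta += params["p0.occ[2]"]
        elif k == 2:
            eta += params["p0.occ[3]"]
        return 1.0 / (1.0 + np.exp(-eta - (params["p0.sex[M]"] if sex == "M" else 0)))

    def sigma_fn(g, sex):
        return np.exp(params["sigma.(Intercept)"]
                      + (params["sigma.sex[M]"] if sex == "M" else 0))

    return mu_fn, p0_fn, sigma_fn


# ---------------------------------------------------------------------------

class TestDetectionProb:
    def test_at_activity_center_equals_p0(self):
        assert scr.detection_prob(0.11, 200.0, 0.0) == pytest.approx(0.11)

    def test_halfnormal_closed_form(self):
        assert scr.detection_prob(0.5, 100.0, 100.0) == pytest.approx(0.5 * np.exp(-0.5))

    def test_vanishes_at_large_distance(self):
        assert scr.detection_prob(0.9, 100.0, 1e6) == pytest.approx(0.0, abs=1e-300)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 2000, 200)
        p = scr.detection_prob(0.3, 250.0, d)
        assert np.all(np.diff(p) < 0)

    def test_nonpositive_sigma_error(self):
        with pytest.raises(ValueError):
            scr.detection_prob(0.5, 0.0, 10.0)


class TestLinearPredictors:
    def test_intercept_only_density_backtransform(self):
        # log-intensity -1.47/pixel is ~16 deer per km^2 at 0.0144 km^2 pixels
        intensity = np.exp(-1.47)
        assert intensity == pytest.approx(0.2299, abs=1e-4)
        assert intensity / 0.0144 == pytest.approx(15.97, abs=0.005)

    def test_identity_links_at_zero(self):
        space, traps, enc = one_pixel_setup()
        nll = scr.SCRLikelihood(scr.ModelSpec(), enc, space, traps)
        log_mu, logit_p0, log_sigma = nll.linear_predictors(
            np.zeros(4), "s1", "F")
        assert np.exp(log_mu[0]) == 1.0
        assert expit(logit_p0[0, 0]) == 0.5
        assert log_sigma == 0.0

    def test_treatment_contrast_addition(self):
        # detection intercept -2.08 plus transitional contrast 0.56
        assert expit(-2.08 + 0.56) == pytest.approx(0.18, abs=0.005)

    def test_unknown_covariate_errors(self):
        space, traps, enc = one_pixel_setup()
        with pytest.raises(ValueError):
            scr.SCRLikelihood(scr.ModelSpec(density="~elevation"), enc, space, traps)


class TestNegLogLikelihood:
    def test_hand_computed_single_cell(self):
        """mu=1, p=0.5, one detection: -logL = -(log mu + log p - mu p)."""
        space, traps, enc = one_pixel_setup()
        nll = scr.SCRLikelihood(scr.ModelSpec(), enc, space, traps)
        v = nll(np.array([0.0, 0.0, np.log(100.0), 30.0]))  # psi -> 1
        assert v == pytest.approx(-(np.log(0.5) - 0.5), abs=1e-6)

    def test_vanishing_density_diverges(self):
        space, traps, enc = one_pixel_setup()
        nll = scr.SCRLikelihood(scr.ModelSpec(), enc, space, traps)
        assert nll(np.array([-40.0, 0.0, np.log(100.0), 30.0])) > 30.0

    def test_matches_bruteforce_oracle_on_random_toys(self):
        checked = 0
        seed = 0
        while checked < 20 and seed < 200:
            seed += 1
            toy = random_toy(seed)
            if toy is None:
                continue
            space, traps, enc, spec, params = toy
            nll = scr.SCRLikelihood(spec, enc, space, traps)
            got = nll(params_vector(nll, params))
            mu_fn, p0_fn, sigma_fn = make_oracle_fns(params)
            want = oracle_neg_log_likelihood(
                enc, list(zip(space.x, space.y)), list(zip(traps.x, traps.y)),
                mu_fn, p0_fn, sigma_fn, expit(params["psi.(Intercept)"]))
            assert got == pytest.approx(want, abs=1e-8), f"toy seed {seed}"
            checked += 1
        assert checked == 20

    def test_invariant_to_trap_relabeling_and_translation(self):
        toy = random_toy(7)
        space, traps, enc, spec, params = toy
        nll = scr.SCRLikelihood(spec, enc, space, traps)
        v0 = nll(params_vector(nll, params))
        # translate all coordinates
        space2 = StateSpace(x=space.x + 5000, y=space.y - 3000, resolution=space.resolution)
        traps2 = TrapArray(ids=traps.ids, x=traps.x + 5000, y=traps.y - 3000)
        nll2 = scr.SCRLikelihood(spec, enc, space2, traps2)
        assert nll2(params_vector(nll2, params)) == pytest.approx(v0, abs=1e-9)
        # relabel traps (reverse order), remapping encounter arrays
        order = np.arange(traps.n_traps)[::-1]
        traps3 = TrapArray(ids=traps.ids[order], x=traps.x[order], y=traps.y[order])
        enc3 = build_encounter_array(
            [DetectionRecord(ind, str(e.sex[i]), str(traps.ids[j]), k + 1, g)
             for g in enc.session_ids
             for e in [enc[g]]
             for i, ind in enumerate(e.individuals)
             for j, k in zip(*np.nonzero(e.y[i]))],
            traps3, {g: enc[g].n_occasions for g in enc.session_ids})
        nll3 = scr.SCRLikelihood(spec, enc3, space, traps3)
        assert nll3(params_vector(nll3, params)) == pytest.approx(v0, abs=1e-9)

    def test_sex_labels_irrelevant_when_parameters_sex_symmetric(self):
        """With psi = 0.5 and no sex terms, relabeling sexes leaves the
        likelihood unchanged."""
        toy = random_toy(13)
        space, traps, enc, _, _ = toy
        spec = scr.ModelSpec(density="~session", detection="~session", sigma="~1")
        nll = scr.SCRLikelihood(spec, enc, space, traps)
        values = {"D.(Intercept)": -0.4, "D.session[B]": 0.2,
                  "p0.(Intercept)": -0.8, "p0.session[B]": -0.2,
                  "sigma.(Intercept)": np.log(150.0), "psi.(Intercept)": 0.0}
        theta = np.array([values[n] for n in nll.names])
        v0 = nll(theta)
        rng = np.random.default_rng(0)
        records = []
        for g in enc.session_ids:
            e = enc[g]
            for i, ind in enumerate(e.individuals):
                sex = rng.choice(["F", "M"])
                for j, k in zip(*np.nonzero(e.y[i])):
                    records.append(DetectionRecord(ind, sex, str(traps.ids[j]), k + 1, g))
        enc2 = build_encounter_array(records, traps,
                                     {g: enc[g].n_occasions for g in enc.session_ids})
        v1 = scr.SCRLikelihood(spec, enc2, space, traps)(theta)
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_wrong_parameter_count_errors(self):
        space, traps, enc = one_pixel_setup()
        nll = scr.SCRLikelihood(scr.ModelSpec(), enc, space, traps)
        with pytest.raises(ValueError):
            nll(np.zeros(3))


@pytest.fixture(scope="module")
def small_fit():
    """A quick ML fit on a reduced clustered design."""
    from deerscr.synthetic import DesignConfig, TruthConfig

    design = DesignConfig(n_cols=2, n_rows=2, drop_clusters=())
    traps = deerscr.gen_design(design)
    space = deerscr.build_state_space(traps, buffer_m=600.0)
    truth = TruthConfig(density_intercept=np.log(25 * 0.0144), density_session={},
                        p0_intercept=-1.2, p0_session={}, log_sigma=np.log(150.0))
    rng = np.random.default_rng(21)
    pop = deerscr.simulate_population(space, truth, ["2016"], rng=rng)
    records = deerscr.simulate_detections(pop, traps, {"2016": 4}, truth, rng=rng)
    enc = build_encounter_array(records, traps, {"2016": 4})
    spec = scr.ModelSpec(density="~1", detection="~1", sigma="~1")
    res = deerscr.fit(spec, enc, space, traps)
    return space, traps, enc, spec, res


class TestFit:
    def test_converges_with_finite_inference(self, small_fit):
        *_, res = small_fit
        assert res.converged
        assert np.isfinite(res.estimates).all()
        assert np.isfinite(res.se).all() and (res.se > 0).all()
        assert res.aic == pytest.approx(2 * res.neg_loglik + 2 * res.K)
        assert res.summary().shape[0] == res.K

    def test_optimum_stable_under_start_perturbation(self, small_fit):
        space, traps, enc, spec, res = small_fit
        rng = np.random.default_rng(5)
        start = res.estimates + rng.uniform(-0.3, 0.3, res.K)
        res2 = deerscr.fit(spec, enc, space, traps, start=start)
        assert res2.neg_loglik == pytest.approx(res.neg_loglik, abs=1e-4)

    def test_estimates_near_truth(self, small_fit):
        *_, res = small_fit
        assert abs(res.coef("p0.(Intercept)") - (-1.2)) < 3 * res.se_of("p0.(Intercept)")
        assert abs(res.coef("sigma.(Intercept)") - np.log(150)) < 3 * res.se_of("sigma.(Intercept)")


class TestPredictDensity:
    def test_homogeneous_surface_is_flat_and_conserves_total(self, small_fit):
        space, traps, enc, spec, res = small_fit
        surf = deerscr.predict_density(res)
        per_pixel = surf.per_pixel
        assert per_pixel["density_km2"].nunique() == 1
        tot = surf.totals.iloc[0]
        assert tot["expected_N"] == pytest.approx(per_pixel["mu"].sum())
        assert tot["density_km2"] == pytest.approx(
            per_pixel["mu"].sum() / space.total_area_km2)
        assert tot["lcl"] <= tot["density_km2"] <= tot["ucl"]
        # per-class prediction equals the overall density for a flat model
        assert surf.per_class["density_km2"].iloc[0] == pytest.approx(tot["density_km2"])


class TestBacktransform:
    def test_logit_and_exp_links(self):
        assert scr.backtransform(-2.08, link="logit") == pytest.approx(0.111, abs=5e-4)
        assert scr.backtransform(5.80, link="exp") == pytest.approx(330.3, abs=0.05)
        assert scr.backtransform(-1.47, link="exp",
                                 pixel_area_km2=0.0144) == pytest.approx(15.97, abs=0.005)

    def test_contrast_is_added_before_inversion(self):
        v = scr.backtransform(-1.47, contrast=-5.55, link="exp", pixel_area_km2=0.0144)
        assert v == pytest.approx(0.062, abs=5e-4)

    def test_check_flags_only_divergent_rows(self):
        rows = [
            {"parameter": "p0", "estimate": -2.08, "link": "logit", "printed": 0.11},
            {"parameter": "D0", "estimate": -1.47, "link": "exp",
             "pixel_area_km2": 0.0144, "printed": 16.03},
        ]
        out = scr.backtransform_check(rows)
        assert bool(out.loc[0, "agrees"]) is True
        assert bool(out.loc[1, "agrees"]) is False  # 15.97 from rounded inputs
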