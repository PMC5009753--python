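import numpy as np
import pandas as pd
import pytest

from phic31rec import (ExperimentDataset, ExperimentDesign, fit_parameters,
                       generate_dataset, objective, robustness_scan)
from phic31rec.fitting import residuals
from phic31rec.synth import TIMECOURSE_MIN


@pytest.fixture(scope="module")
def small_design():
    """Just the two time-course arms: 32 cells, 2 simulations per objective."""
    cells = [("pPB", 400.0, 0.0, t / 60.0) for t in TIMECOURSE_MIN]
    cells += [("pLR", 400.0, 800.0, t / 60.0) for t in TIMECOURSE_MIN]
    return ExperimentDesign(cells)


@pytest.fixture(scope="module")
def clean_dataset(ref_params, small_design):
    return generate_dataset(ref_params, small_design, noise_sd=0.0, seed=0)


def test_noise_free_objective_is_zero(ref_params, clean_dataset):
    assert objective(ref_params, clean_dataset) < 1e-10


def test_objective_requires_closed_params(ref_params, clean_dataset):
    broken = ref_params.with_updates(K={"r1": ref_params.K["r1"] * 2})
    with pytest.raises(ValueError, match="closed"):
        objective(broken, clean_dataset)


def test_objective_invariant_to_row_order(ref_params, clean_dataset):
    shuffled = ExperimentDataset(
        clean_dataset.table.sample(frac=1.0, random_state=5)
        .reset_index(drop=True))
    assert objective(ref_params, shuffled) == pytest.approx(
        objective(ref_params, clean_dataset), abs=1e-12)


def test_weighted_objective_halves_under_duplication(ref_params, small_design):
    ds = generate_dataset(ref_params, small_design, noise_sd=0.02, seed=7)
    base = objective(ref_params, ds, weighted=True)
    # duplicating every observation at sqrt(2)-inflated sd leaves the
    # weighted sum unchanged
    t = ds.table
    dup = pd.concat([t, t.assign(sd=t.sd)], ignore_index=True)
    dup["sd"] = dup["sd"] * np.sqrt(2.0)
    assert objective(ref_params, ExperimentDataset(dup),
                     weighted=True) == pytest.approx(base, rel=1e-9)


def test_label_swap_breaks_fit_by_orders_of_magnitude(ref_params, small_design):
    ds = generate_dataset(ref_params, small_design, noise_sd=0.0, seed=0)
    swapped = ds.table.copy()
    swapped["substrate"] = swapped["substrate"].map({"pPB": "pLR",
                                                     "pLR": "pPB"})
    swapped[["int_total_nM", "rdf_total_nM"]] = \
        swapped[["rdf_total_nM", "int_total_nM"]].to_numpy()[:, ::-1]
    obj = objective(ref_params, ExperimentDataset(swapped))
    assert obj > 1e3 * max(objective(ref_params, ds), 1e-9)


def test_chi_square_expectation_of_noisy_objective(ref_params, small_design):
    """Unweighted SSR against cell means of n=3 draws: E = cells * sd^2 / n."""
    sd, n_seeds = 0.03, 20
    vals = []
    truth = generate_dataset(ref_params, small_design, noise_sd=0.0, seed=0)
    truth_frac = truth.table.fraction_recombinant.to_numpy()
    for seed in range(n_seeds):
        ds = generate_dataset(ref_params, small_design, noise_sd=sd, seed=seed)
        # residuals against the frozen truth avoid re-simulating every seed
        r = ds.table.fraction_recombinant.to_numpy() - truth_frac
        vals.append(float(r @ r))
    expected = len(small_design) * sd ** 2 / small_design.replicates
    assert np.mean(vals) == pytest.approx(expected, rel=0.15)


def test_fit_rejects_derived_constants(ref_params, clean_dataset):
    with pytest.raises(ValueError, match="closure-derived"):
        fit_parameters(clean_dataset, ref_params, ["K_s2"])


def test_fit_noise_free_truth_is_fixed_point(ref_params, clean_dataset):
    res = fit_parameters(clean_dataset, ref_params, ["K_r1", "kf_r1"],
                         seed=1)
    assert res.objective < 1e-10
    assert res.params.is_closed()
    for name in ("K_r1", "kf_r1"):
        assert res.params.get_flat(name) == pytest.approx(
            ref_params.get_flat(name), rel=1e-6)


def test_fit_recovers_perturbed_constant(ref_params, clean_dataset):
    start = ref_params.set_flat("K_r1", ref_params.K["r1"] * 1.3)
    res = fit_parameters(clean_dataset, start, ["K_r1"], seed=1)
    assert res.params.K["r1"] == pytest.approx(ref_params.K["r1"], rel=1e-3)
    assert res.objective < 1e-8


def test_every_candidate_evaluated_closed(ref_params, clean_dataset,
                                          monkeypatch):
    import phic31rec.fitting as fitting
    seen = []
    original = residuals

    def spy(params, dataset, weighted=False):
        seen.append(max(params.closure_log_products(), key=abs))
        return original(params, dataset, weighted=weighted)

    monkeypatch.setattr(fitting, "residuals", spy)
    fitting.fit_parameters(clean_dataset, ref_params, ["K_r1"], seed=1,
                           max_nfev=4)
    assert seen and max(abs(v) for v in seen) < 1e-12


def test_robustness_identity_fold_is_zero(ref_params):
    df = robustness_scan(ref_params, fold=1.0, n_times=8,
                         free_names=["K_r1", "kf_s1", "K_b3"])
    assert np.allclose(df["max_abs_rel_change_pct"], 0.0)


def test_robustness_direct_mode_runs_unclosed(ref_params):
    df = robustness_scan(ref_params, fold=2.0, n_times=8, mode="direct",
                         free_names=["K_r1"])
    assert (df["error"] == "").all()
    assert df["max_abs_rel_change_pct"].notna().all()


def test_dataset_validation():
    bad = pd.DataFrame({"substrate": ["pPB"], "int_total_nM": [400.0],
                        "rdf_total_nM": [0.0], "time_h": [1.0],
                        "fraction_recombinant": [1.4], "sd": [0.01],
                        "n": [3]})
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ExperimentDataset(bad)
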