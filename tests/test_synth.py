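import numpy as np
import pytest

from phic31rec import (ExperimentDataset, ExperimentDesign, default_design,
                       generate_dataset)
from phic31rec.fitting import predict
from phic31rec.synth import TIMECOURSE_MIN


def test_default_design_matches_study_shape():
    d = default_design()
    assert len(d) == 92
    assert d.replicates == 3
    assert d.dna_conc == 10.0
    times = [c[3] for c in d.cells]
    assert all(t > 0 for t in times)
    # each time-course arm contains the 3-h endpoint, so course and
    # endpoint readouts coincide there
    assert ("pPB", 400.0, 0.0, 3.0) in d.cells
    assert ("pLR", 400.0, 800.0, 3.0) in d.cells
    # two 16-point courses + 12 integrase points + 12x4 integrase-RDF grid
    assert sum(c[3] != 3.0 for c in d.cells) == 2 * (len(TIMECOURSE_MIN) - 1)


def test_design_yaml_roundtrip(tmp_path):
    d = default_design()
    d.to_yaml(tmp_path / "design.yaml")
    back = ExperimentDesign.from_yaml(tmp_path / "design.yaml")
    assert back.cells == d.cells
    assert back.replicates == d.replicates


def test_noise_free_dataset_equals_model_predictions(ref_params):
    ds = generate_dataset(ref_params, default_design(), noise_sd=0.0, seed=9)
    assert np.allclose(ds.table.fraction_recombinant.to_numpy(),
                       predict(ref_params, ds), atol=1e-12)
    assert (ds.table.sd == 0.0).all()


def test_generation_is_byte_identical_for_fixed_seed(ref_params, tmp_path):
    paths = []
    for k in (1, 2):
        ds = generate_dataset(ref_params, default_design(), seed=123)
        p = tmp_path / f"ds{k}.csv"
        ds.to_csv(p, {"seed": 123})
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_fractions_always_within_bounds(ref_params):
    small = ExperimentDesign([("pPB", 400.0, 0.0, t / 60.0)
                              for t in TIMECOURSE_MIN], replicates=5,
                             noise_sd=0.5)
    ds = generate_dataset(ref_params, small, seed=4)
    f = ds.table.fraction_recombinant.to_numpy()
    assert np.all((f >= 0.0) & (f <= 1.0))


def test_replicate_noise_matches_specified_sd(ref_params):
    """Pooled replicate SD reproduces the generator sd away from [0,1]."""
    design = ExperimentDesign([("pPB", 400.0, 0.0, t / 60.0)
                               for t in TIMECOURSE_MIN]
                              + [("pLR", 400.0, 800.0, t / 60.0)
                                 for t in TIMECOURSE_MIN], replicates=30)
    ds = generate_dataset(ref_params, design, noise_sd=0.03, seed=11)
    t = ds.table
    mid = t[(t.fraction_recombinant > 0.1) & (t.fraction_recombinant < 0.9)]
    assert len(mid) >= 15
    pooled = float(np.sqrt(np.mean(mid.sd.to_numpy() ** 2)))
    assert pooled == pytest.approx(0.03, rel=0.10)


def test_dataset_csv_roundtrip_preserves_values(ref_params, tmp_path):
    ds = generate_dataset(ref_params, default_design(), seed=2)
    path = tmp_path / "ds.csv"
    ds.to_csv(path, {"seed": 2})
    back = ExperimentDataset.from_csv(path)
    assert back.provenance == "synthetic(seed=2)"
    a = ds.table.fraction_recombinant.to_numpy()
    b = back.table.fraction_recombinant.to_numpy()
    assert np.allclose(a, b, rtol=0, atol=1e-12)
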