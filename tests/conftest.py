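import numpy as np
import pytest

from tcgsea import RpkmTable, make_toy_kgml


def build_rpkm(control, treatment, kids=None, time_points=None, ids=None):
    """Small helper: build an RpkmTable from dense arrays."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    n, t = control.shape
    return RpkmTable(
        np.array(ids or [f"seq{i}" for i in range(n)], dtype=object),
        np.array(kids if kids is not None else [f"K{i + 1:05d}" for i in range(n)],
                 dtype=object),
        control,
        treatment,
        np.array(time_points if time_points is not None else np.arange(t) * 24.0),
    )


def random_rpkm(rng, n=12, t=4, kids=None):
    return build_rpkm(
        rng.lognormal(2.0, 1.0, (n, t)),
        rng.lognormal(2.0, 1.0, (n, t)),
        kids=kids,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def toy_kgml(tmp_path_factory):
    """Default toy pathway bundle on disk plus its ground-truth manifest."""
    out = tmp_path_factory.mktemp("kgml")
    manifest = make_toy_kgml(out_dir=out)
    return out, manifest
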