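"""Packaged measurement tables and best-fit parameters, with checksums."""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd
import yaml

from .dataprep import ObservedDataset
from .params import CascadeParameters

__all__ = ["load_observed", "load_best_fit_params", "load_fixtures"]

_CHECKSUMS = {
    "table2_counts.csv": "a5563fa4da51ef72b21b808de92fdb2187e205f7b51ee12c40cb6769f49efa72",
    "table3_proportions.csv": "709d45e35536b94c778ee90587c3aa80cb43e4edee21b9e2aa85d1884a0679fa",
    "best_fit_params.yaml": "b6ea6bc07d9fbba07423dcc90011ccb56f8fbe25e6d4cbb86415a8ea56d29b2b",
}


class FixtureChecksumError(RuntimeError):
    pass


def _read(name: str) -> bytes:
    data = (resources.files("neurocascade") / "fixtures" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureChecksumError(
            f"fixture {name} is corrupted (sha256 {digest}, expected {_CHECKSUMS[name]})"
        )
    return data


def load_observed() -> ObservedDataset:
    """The packaged pulse-chase dataset (counts and per-type proportions).

    Proportions are converted from the printed x100 scale to the 0-1 scale.
    """
    import io

    counts = pd.read_csv(io.BytesIO(_read("table2_counts.csv")))
    props = pd.read_csv(io.BytesIO(_read("table3_proportions.csv")))
    for col in props.columns:
        if col.endswith("_mean") or col.endswith("_sem"):
            props[col] = props[col] / 100.0
    return ObservedDataset(counts=counts, proportions=props)


def load_best_fit_params() -> CascadeParameters:
    """The packaged best-fit parameter set (unit influx; calibrate at use)."""
    d = yaml.safe_load(_read("best_fit_params.yaml"))
    return CascadeParameters.from_dict(d)


def load_fixtures():
    """Convenience: (ObservedDataset, best-fit CascadeParameters)."""
    return load_observed(), load_best_fit_params()
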