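"""Config-file ingestion for model and experiment parameters.

Accepts flat key/value files in YAML or JSON (keys: alpha, beta, rho, tau,
t0, direction, targets, n_trials, dt, seed, learning).  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ParameterError
from .experiments import ExperimentSpec
from .learning import LearningConfig

_SPEC_KEYS = {
    "alpha", "beta", "rho", "tau", "t0", "direction",
    "targets", "n_trials", "dt", "seed", "learning",
}
_LEARN_KEYS = {"eta", "n_iterations", "batch", "tol", "window", "seed"}


def load_params(path: str | Path) -> dict:
    """Read a YAML or JSON parameter file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def experiment_spec_from_file(path: str | Path, **overrides) -> ExperimentSpec:
    """Build an ExperimentSpec from a config file plus keyword overrides."""
    params = load_params(path) or {}
    if not isinstance(params, dict):
        raise ParameterError(f"config {path} must be a mapping")
    params.update(overrides)
    learn = params.pop("learning_config", None)
    unknown = set(params) - _SPEC_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if "targets" in params:
        params["targets"] = tuple(float(t) for t in params["targets"])
    if learn is not None:
        bad = set(learn) - _LEARN_KEYS
        if bad:
            raise ParameterError(f"unknown learning_config keys: {sorted(bad)}")
        params["learning_config"] = LearningConfig(**learn)
    return ExperimentSpec(**params)
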