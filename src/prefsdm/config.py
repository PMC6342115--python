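"""Plain-text run configuration shared by all CLI subcommands.

One INI-style schema (parsed with :mod:`configparser`) with sections
``[run]``, ``[scenario]``, ``[model]`` and ``[study]``; CLI flags override
file values.  Every run writes a JSON manifest (config hash, seed,
package and library versions) sufficient to reproduce it.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import platform
from pathlib import Path

from .exceptions import FormatError
from .grids import GridGeometry
from .model import ModelSpec, PriorSpec
from .random_fields import MaternHyperparams
from .sampling import ScenarioConfig
from .evaluation import StudyConfig

_SECTIONS = ("run", "scenario", "model", "study")


def read_config(path) -> dict:
    """Parse a config file into a {section: {key: str}} mapping."""
    parser = configparser.ConfigParser()
    try:
        with open(path) as fh:
            parser.read_file(fh)
    except (configparser.Error, OSError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    out = {}
    for section in parser.sections():
        if section not in _SECTIONS:
            raise FormatError(f"unknown config section [{section}] in {path}")
        out[section] = dict(parser.items(section))
    return out


def merge_options(config: dict, section: str, overrides: dict) -> dict:
    """Section values with non-None CLI overrides applied on top."""
    merged = dict(config.get(section, {}))
    for key, value in overrides.items():
        if value is not None:
            merged[key] = value
    return merged


def _get(opts, key, cast, default):
    if key not in opts or opts[key] in ("", None):
        return default
    try:
        if cast is bool:
            return str(opts[key]).strip().lower() in ("1", "true", "yes", "on")
        return cast(opts[key])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"config key {key!r}: cannot interpret {opts[key]!r}") from exc


def scenario_from_options(opts: dict) -> ScenarioConfig:
    nx = _get(opts, "nx", int, 100)
    ny = _get(opts, "ny", int, 100)
    cell = _get(opts, "cell_size", float, 1.0)
    grid = GridGeometry(nx, ny, cell_size=cell)
    range_ = _get(opts, "range", float, 0.2 * grid.width)
    sigma2 = _get(opts, "sigma2", float, 1.0)
    return ScenarioConfig(
        grid=grid,
        hyper=MaternHyperparams(sigma2=sigma2, range_=range_),
        n=_get(opts, "n", int, 100),
        b=_get(opts, "b", float, 1.0),
        family=_get(opts, "family", str, "gamma"),
        shape=_get(opts, "shape", float, 10.0),
        noise_sd=_get(opts, "noise_sd", float, 0.1),
        intercept=_get(opts, "intercept", float, 0.0),
    )


def model_from_options(opts: dict) -> tuple[ModelSpec, dict]:
    """A ModelSpec plus fitter keyword arguments from a config section."""
    style = _get(opts, "prior_style", str, "gaussian")
    priors = PriorSpec(
        spatial_style=style,
        prior_median_range=_get(opts, "prior_median_range", float, None),
        prior_median_sd=_get(opts, "prior_median_sd", float, 1.0),
        pc_range=(
            (_get(opts, "pc_range_r0", float, None), _get(opts, "pc_range_p", float, 0.25))
            if style == "pc"
            else None
        ),
        pc_sigma=(
            (_get(opts, "pc_sigma_s0", float, None), _get(opts, "pc_sigma_p", float, 0.1))
            if style == "pc"
            else None
        ),
    )
    model = _get(opts, "model", str, "preferential")
    if model not in ("preferential", "nonpreferential"):
        raise FormatError(f"model must be preferential or nonpreferential, got {model!r}")
    spec = ModelSpec(
        mark_family=_get(opts, "family", str, "gamma"),
        preferential=model == "preferential",
        priors=priors,
        pad_cells=_get(opts, "pad_cells", int, None),
    )
    fit_kwargs = {"outer_maxfev": _get(opts, "outer_maxfev", int, 150)}
    return spec, fit_kwargs


def study_from_options(opts: dict) -> StudyConfig:
    return StudyConfig(
        replicates=_get(opts, "replicates", int, 30),
        nx=_get(opts, "nx", int, 32),
        ny=_get(opts, "ny", int, 32),
        range_=_get(opts, "range", float, None),
        sigma2=_get(opts, "sigma2", float, 1.0),
        n=_get(opts, "n", int, 100),
        b=_get(opts, "b", float, 1.0),
        family=_get(opts, "family", str, "gamma"),
        shape=_get(opts, "shape", float, 10.0),
        noise_sd=_get(opts, "noise_sd", float, 0.1),
        intercept=_get(opts, "intercept", float, 0.0),
        outer_maxfev=_get(opts, "outer_maxfev", int, 150),
        dic_draws=_get(opts, "dic_draws", int, 1000),
    )


def write_manifest(out_dir, *, command: str, seed: int, config: dict, artifacts: list) -> Path:
    """Record everything needed to reproduce a run."""
    import numpy
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "artifacts": artifacts,
        "versions": {
            "prefsdm": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
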