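"""Loader for the shipped fiber/standard-base parameter file."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = ["load_params", "standard_base_coords", "fiber_step_params"]


@lru_cache(maxsize=1)
def load_params() -> dict:
    text = resources.files("strandkit.data").joinpath("fiber_params.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=8)
def standard_base_coords(base: str):
    """(names, coords) of the standard-frame heavy atoms of one base (incl. C1')."""
    table = load_params()["standard_bases"][base]
    names = tuple(table.keys())
    coords = np.array([table[n] for n in names], dtype=float)
    return names, coords


def fiber_step_params(form: str) -> dict:
    forms = load_params()["steps"]
    if form not in forms:
        raise ValueError(f"unknown helix form {form!r}; expected one of {sorted(forms)}")
    return dict(forms[form])
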