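"""Loaders for the versioned data files packaged with featkit."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("featkit.data").joinpath(name).open() as fh:
        return json.load(fh)


def physico_scales() -> dict[str, dict[str, float]]:
    return _load("physico_scales.json")["scales"]


def max_asa_table(kind: str = "theoretical") -> dict[str, float]:
    tables = _load("max_asa.json")
    if kind not in tables or kind.startswith("_"):
        raise KeyError(f"unknown max ASA table {kind!r}")
    return tables[kind]


def background_freqs(kind: str = "blosum62") -> dict[str, float]:
    tables = _load("background_freqs.json")
    if kind not in tables or kind.startswith("_"):
        raise KeyError(f"unknown background distribution {kind!r}")
    return tables[kind]
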