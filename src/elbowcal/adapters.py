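"""Adapters for external datasets.

The published elbow-calibration dataset (optical reference + IMU recordings,
deposited on Zenodo) can in principle be mapped onto this package's trial
representation to re-run the study pipeline on real recordings. Its internal
layout is isolated here: directories already in the package's native trial
schema load directly; anything else raises an explicit unsupported-format
report listing what was found, so adding a translator for the deposit's
layout touches only this module.
"""

from __future__ import annotations

from pathlib import Path

from .io import load_study
from .simulate import SyntheticTrial

__all__ = ["UnsupportedFormatError", "load_zenodo_adapter"]


class UnsupportedFormatError(ValueError):
    """The directory layout is not one the adapter knows how to read."""


def load_zenodo_adapter(path) -> dict[str, dict[str, SyntheticTrial]]:
    """Load a local copy of the study deposit into trial collections.

    Currently supports the package's native study layout (per-subject trial
    directories plus ``study.json``); a deposit in any other layout raises
    :class:`UnsupportedFormatError` describing the top-level contents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset directory not found: {path}")
    if (path / "study.json").exists():
        return load_study(path)
    entries = sorted(p.name for p in path.iterdir())[:20]
    raise UnsupportedFormatError(
        "unrecognized dataset layout: no study.json index found. "
        f"Top-level entries: {entries}. Mapping this layout requires a "
        "format translator in elbowcal.adapters."
    )
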