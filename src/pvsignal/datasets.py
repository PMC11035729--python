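"""Bundled reference lists: curated subgroup PT lists and a starter
exclusion list."""

from __future__ import annotations

from importlib import resources

from .io import load_pt_list

_SUBGROUPS = {
    "bleeding": "bleeding_pts.txt",
    "respiratory": "respiratory_pts.txt",
    "cardiac": "cardiac_pts.txt",
}


def _load(name: str) -> set[str]:
    ref = resources.files("pvsignal.data").joinpath(name)
    with resources.as_file(ref) as path:
        return load_pt_list(path)


def subgroup_pts(name: str) -> set[str]:
    """Curated PT list for a clinical subgroup view.

    ``name`` is one of ``bleeding``, ``respiratory``, ``cardiac``.
    """
    if name not in _SUBGROUPS:
        raise KeyError(f"unknown subgroup {name!r}; have {sorted(_SUBGROUPS)}")
    return _load(_SUBGROUPS[name])


def starter_exclusions() -> set[str]:
    """Seed exclusion list (non-reference, disease-related, medication-error
    terms); studies are expected to extend it."""
    return _load("starter_exclusions.txt")
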