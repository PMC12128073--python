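"""Bundled illustrative model library.

The models shipped here mirror the covariate composition typical of the
pediatric vancomycin literature (weight + postmenstrual age + serum
creatinine on clearance for neonates; weight with or without creatinine
clearance for older children) but their parameter values are illustrative
choices of this package, not re-encodings of any published model.
"""

from __future__ import annotations

from importlib import resources

from ..modelspec import ModelSpec, load_model

__all__ = ["bundled_model_names", "load_bundled_model", "load_bundled_models"]


def bundled_model_names() -> list[str]:
    root = resources.files(__package__)
    return sorted(p.name[:-5] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_bundled_model(name: str) -> ModelSpec:
    path = resources.files(__package__) / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(
            f"no bundled model {name!r}; available: {bundled_model_names()}")
    with resources.as_file(path) as p:
        return load_model(p)


def load_bundled_models(cohort: str | None = None) -> list[ModelSpec]:
    """All bundled models, optionally filtered to one cohort label."""
    models = [load_bundled_model(n) for n in bundled_model_names()]
    if cohort is not None:
        models = [m for m in models if m.cohort in (cohort, "AB")]
    return models
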