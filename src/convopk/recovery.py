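"""Simulate-then-refit recovery experiments on the product presets.

The central validation of the fitting machinery: simulate mean
concentration profiles at a product's study doses from its published
parameter set, perturb them with proportional noise, refit the
convolution model from displaced starting values, and compare the
estimates with the generating truth.  Because the per-seed maximum
likelihood estimates scatter (the release-mixture parameters carry
relative standard errors of up to ~20 % at 5 % noise), recovery is
summarized by the across-seed mean estimate.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datasets import SynthSpec, generate_dataset
from .estimators import FitSpec, fit_pooled
from .presets import get_preset

__all__ = ["recover_preset_params"]


def recover_preset_params(
    preset_name: str,
    seeds,
    *,
    cv: float = 0.05,
    n_starts: int = 4,
    init_offset: float = 1.3,
    quiet: bool = True,
) -> dict[str, np.ndarray]:
    """Fit the dual-Weibull convolution model to noisy synthetic datasets.

    For each seed: simulate the preset's dose groups on its sampling
    schedule, add ``cv`` proportional Gaussian noise, and refit all seven
    parameters by pooled proportional-error ML started ``init_offset``
    (default 30 % high) away from truth with ``n_starts`` jittered starts.

    Returns ``{parameter: array of per-seed estimates}`` plus a ``"truth"``
    entry mapping parameter names to generating values.
    """
    preset = get_preset(preset_name)
    truth = dict(preset.release.as_dict())
    truth.pop("family")
    truth.update(CL=preset.disposition.CL, V=preset.disposition.V)
    init = {k: float(v) * init_offset for k, v in truth.items()}
    init["FF"] = min(init["FF"], 0.95)

    estimates: dict[str, list[float]] = {k: [] for k in truth}
    for seed in seeds:
        ds = generate_dataset(SynthSpec(preset=preset_name, cv=cv, seed=int(seed)))
        spec = FitSpec(
            model="conv-weibull2", init=init, n_starts=n_starts, seed=int(seed)
        )
        with warnings.catch_warnings():
            if quiet:
                warnings.simplefilter("ignore")
            fr = fit_pooled(ds, spec)
        for k in estimates:
            estimates[k].append(fr.params[k])
    out = {k: np.asarray(v) for k, v in estimates.items()}
    out["truth"] = truth  # type: ignore[assignment]
    return out
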