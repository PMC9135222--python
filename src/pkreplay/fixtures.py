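"""Synthetic PK data generation.

The original mouse PK datasets behind the replicated profiles are not
published, so fixtures are generated from known parameters: model values
under a regimen, optionally corrupted with multiplicative lognormal noise
of a given coefficient of variation. All parameter sets shipped here are
synthetic stand-ins chosen to be pharmacologically plausible, not fitted
values from any study.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .pk import (ConcentrationSeries, DosingRegimen, PKParameters, SeriesMeta,
                 concentration_regimen)

__all__ = ["generate_pk_fixture", "SYNTHETIC_PARAMS"]

#: Synthetic one-compartment parameter sets (1/h, 1/h, uM per mg/kg).
#: "erki" mimics a rapidly absorbed, moderately cleared oral kinase
#: inhibitor dosed QD; its scale is chosen so a 50 mg/kg dose peaks near
#: 2.16 uM. "dnapki" mimics a BID partner with faster clearance.
SYNTHETIC_PARAMS: dict[str, PKParameters] = {
    "erki": PKParameters(ka=1.2, ke=0.18, scale=0.0604),
    "dnapki": PKParameters(ka=1.5, ke=0.35, scale=0.0300),
}


def generate_pk_fixture(params: PKParameters, regimen: DosingRegimen,
                        times: np.ndarray, noise_cv: float = 0.0,
                        seed: int | None = None, *,
                        drug: str = "", unit: str = "uM",
                        series_id: str = "") -> ConcentrationSeries:
    """Noisy synthetic observations of a regimen's concentration curve.

    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` and unit mean, deterministic per ``seed`` (required when
    noise_cv > 0). The series is annotated with the regimen's per-event
    dose amount for use in dose-proportional fitting.
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if noise_cv > 0 and seed is None:
        raise InvalidParameterError("seed is required when noise_cv > 0")
    times = np.asarray(times, dtype=float)
    conc = np.atleast_1d(concentration_regimen(params, regimen, times))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        rng = np.random.default_rng(seed)
        conc = conc * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=conc.shape)
    dose = regimen.events[0].amount if regimen.events else float("nan")
    return ConcentrationSeries(times, conc,
                               SeriesMeta(drug=drug, dose=dose, unit=unit,
                                          series_id=series_id))
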