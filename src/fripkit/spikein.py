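"""Spike-in-based background estimation and FRiP denoising.

With spike-in calibration, the scaled read counts of an unperturbed sample
(R_UT) and a depleted sample (R_dep) are directly comparable. Under the
constant-background model, the depleted count decomposes into surviving
signal plus unchanged background, which solves to

    f_UT = (R_dep/R_UT - gamma) / (1 - gamma)

where gamma is the fraction of target protein remaining after depletion
(supplied by the user, e.g. from quantitative western blot or imaging). The
naive estimate R_dep/R_UT ignores gamma and overestimates the background
whenever depletion is incomplete. A background fraction plus the genome
fraction in peaks (rho) then denoises an observed FRiP by removing the
uniform background from numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .biochem import background_fraction_at_abundance

__all__ = [
    "SpikeInPair",
    "FripRecord",
    "calibrated_reads",
    "estimate_f_UT",
    "naive_background_estimate",
    "f_dep_from_f_UT",
    "denoise_frip",
    "batch_correct",
]


@dataclass(frozen=True)
class SpikeInPair:
    """Spike-in calibrated read counts before/after depletion.

    ``gamma`` is the relative target abundance remaining after depletion
    (0 = complete removal).
    """

    R_UT: float
    R_dep: float
    gamma: float

    def __post_init__(self) -> None:
        if self.R_UT <= 0:
            raise ValueError("R_UT must be positive")
        if self.R_dep < 0:
            raise ValueError("R_dep must be nonnegative")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")


@dataclass(frozen=True)
class FripRecord:
    """An observed FRiP with the background fraction and peak fraction used
    to denoise it."""

    frip: float
    rho: float
    f: float

    def __post_init__(self) -> None:
        for name in ("frip", "rho", "f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def calibrated_reads(
    primary_count: float, spikein_count: float, scale_constant: float = 1e6
) -> float:
    """Spike-in calibrated read count: ``primary * scale / spikein``
    (per-spike-in-million by default). Downstream estimates use only ratios
    of calibrated counts, so the constant cancels."""
    if spikein_count <= 0:
        raise ValueError("spikein_count must be positive")
    if primary_count < 0:
        raise ValueError("primary_count must be nonnegative")
    return primary_count * scale_constant / spikein_count


def estimate_f_UT(pair: SpikeInPair) -> float:
    """Unperturbed background fraction from a depletion pair.

    Raises a model-violation error when ``R_dep/R_UT < gamma``: more signal
    survived than the stated depletion allows, so the constant-background
    model cannot hold for these inputs.
    """
    r = pair.R_dep / pair.R_UT
    if r < pair.gamma - 1e-12:
        raise ValueError(
            f"R_dep/R_UT = {r:.4g} < gamma = {pair.gamma:.4g}: "
            "inconsistent with the constant-background model"
        )
    return (r - pair.gamma) / (1.0 - pair.gamma)


def naive_background_estimate(pair: SpikeInPair) -> float:
    """The simple calibrated-read ratio ``R_dep/R_UT``, ignoring leftover
    target. Exact only at complete depletion; otherwise it overestimates the
    background."""
    return pair.R_dep / pair.R_UT


def f_dep_from_f_UT(f_UT: float, gamma: float) -> float:
    """Background fraction in the depleted sample:
    ``f_UT / (gamma*(1-f_UT) + f_UT)``."""
    if not 0.0 <= f_UT < 1.0:
        raise ValueError("f_UT must be in [0, 1)")
    return background_fraction_at_abundance(f_UT, gamma, "uniform")


def denoise_frip(frip_obs: float, f: float, rho: float) -> float:
    """Remove the uniform-background contribution from an observed FRiP:
    ``(frip_obs - f*rho) / (1 - f)``.

    A result outside [0, 1] is returned as-is with a warning — it indicates
    an inconsistent ``f`` or ``rho`` and is diagnostic, so it is not clipped.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("f must be in [0, 1)")
    for name, v in (("frip_obs", frip_obs), ("rho", rho)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    out = (frip_obs - f * rho) / (1.0 - f)
    if not -1e-9 <= out <= 1.0 + 1e-9:  # roundoff margin
        warnings.warn(
            f"denoised FRiP {out:.4g} outside [0, 1]; "
            "check the background fraction and rho",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def batch_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Vector version for tables with columns sample, R_UT, R_dep, gamma,
    frip, rho; adds f_UT, f_dep and frip_denoised columns."""
    required = {"sample", "R_UT", "R_dep", "gamma", "frip", "rho"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    f_ut, f_dep, den = [], [], []
    for row in table.itertuples():
        pair = SpikeInPair(float(row.R_UT), float(row.R_dep), float(row.gamma))
        f = estimate_f_UT(pair)
        f_ut.append(f)
        f_dep.append(
            background_fraction_at_abundance(
                f, float(row.gamma), "uniform", allow_zero_gamma=True
            )
        )
        den.append(denoise_frip(float(row.frip), f, float(row.rho)))
    out["f_UT"] = f_ut
    out["f_dep"] = f_dep
    out["frip_denoised"] = den
    return out
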