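"""Kinetic phenotype profiles of the wild-type receptor and the four
transmembrane-domain point mutants (beta2 G254V, alpha1 G258V,
beta2 L296V, alpha1 L300V) of the alpha1-beta2-gamma2 GABA_A receptor.

Each profile bundles the published summary statistics that the synthetic
data generator reproduces: macroscopic descriptors of the saturating-GABA
response (10-90% rise time; biexponential desensitization parameters and
the FR10/FR300/FR500 remaining fractions; mean deactivation time
constant), the exponential-mixture parameters of apparent shut and open
time distributions, cluster open-probability mode structure, and burst
statistics. Wild-type macroscopic recordings exist in two configurations —
excised patch (fast solution exchange) and lifted cell (slower exchange,
the control condition for beta2 G254V).

These are per-patch averages; they serve as generator targets and as
worked-example inputs, not as fitted model rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MacroTargets:
    """Descriptor targets for one receptor/configuration (ms, fractions)."""

    rise_time_ms: float
    fr10: float
    fr300: float
    fr500: float
    tau_fast_ms: float
    tau_slow_ms: float
    a_fast: float
    a_slow: float
    c: float
    tau_deact_ms: float

    def normalized_amplitudes(self) -> tuple[float, float, float]:
        """(a_fast, a_slow, c) rescaled to sum exactly to 1 (printed values
        round to within 0.02 of 1)."""
        tot = self.a_fast + self.a_slow + self.c
        return (self.a_fast / tot, self.a_slow / tot, self.c / tot)

    def decay(self, t_ms) -> np.ndarray:
        """Normalized biexponential-plus-constant decay at t ms after peak,
        evaluated with the printed (un-renormalized) amplitudes."""
        t = np.asarray(t_ms, dtype=float)
        return (self.a_fast * np.exp(-t / self.tau_fast_ms)
                + self.a_slow * np.exp(-t / self.tau_slow_ms) + self.c)


@dataclass(frozen=True)
class MixtureTargets:
    taus_ms: tuple[float, ...]
    weights: tuple[float, ...]

    def weighted_mean_ms(self) -> float:
        return float(np.dot(self.taus_ms, self.weights))


@dataclass(frozen=True)
class PhenotypeProfile:
    label: str
    macro: MacroTargets
    shut_mix: MixtureTargets | None = None
    open_mix: MixtureTargets | None = None
    #: (P_open level, share) of cluster activity modes; first = predominant
    modes: tuple[tuple[float, float], ...] = ()
    burst_popen: float = np.nan
    burst_length_ms: float = np.nan
    printed_mean_open_ms: float = np.nan


PROFILES: dict[str, PhenotypeProfile] = {}


def _register(p: PhenotypeProfile) -> None:
    PROFILES[p.label] = p


_register(PhenotypeProfile(
    label="WT-excised",
    macro=MacroTargets(0.41, 0.30, 0.15, 0.13, 2.27, 127.98,
                       0.70, 0.15, 0.14, 383.87),
    shut_mix=MixtureTargets((0.04, 0.26, 1.55, 20.42), (0.57, 0.32, 0.10, 0.01)),
    open_mix=MixtureTargets((1.02, 2.86), (0.55, 0.45)),
    modes=((0.69, 1.0),),
    burst_popen=0.69, burst_length_ms=140.29,
    printed_mean_open_ms=1.92,
))
_register(PhenotypeProfile(
    label="WT-lifted",
    macro=MacroTargets(1.83, 0.60, 0.42, 0.36, 4.82, 294.69,
                       0.38, 0.26, 0.36, 173.36),
))
_register(PhenotypeProfile(
    label="b2G254V",
    macro=MacroTargets(1.50, 0.45, 0.28, 0.26, 2.94, 158.48,
                       0.64, 0.15, 0.22, 375.42),
    shut_mix=MixtureTargets((0.05, 0.36, 2.26, 19.25), (0.68, 0.17, 0.10, 0.04)),
    open_mix=MixtureTargets((0.88, 3.06), (0.42, 0.58)),
    modes=((0.66, 0.61), (0.90, 0.26), (0.16, 0.13)),
    burst_popen=0.73, burst_length_ms=57.32,
    printed_mean_open_ms=2.22,
))
_register(PhenotypeProfile(
    label="a1G258V",
    macro=MacroTargets(0.66, 0.56, 0.26, 0.18, 3.71, 247.19,
                       0.42, 0.41, 0.15, 93.40),
    shut_mix=MixtureTargets((0.23, 0.85, 3.41), (0.08, 0.87, 0.05)),
    open_mix=MixtureTargets((0.55, 1.39), (0.82, 0.18)),
    modes=((0.33, 1.0),),
    burst_popen=0.45, burst_length_ms=22.27,
    printed_mean_open_ms=0.68,
))
_register(PhenotypeProfile(
    label="b2L296V",
    macro=MacroTargets(0.64, 0.43, 0.29, 0.26, 4.90, 313.09,
                       0.61, 0.15, 0.24, 36.03),
    shut_mix=MixtureTargets((0.19, 0.88, 2.24), (0.08, 0.69, 0.22)),
    open_mix=MixtureTargets((0.12, 0.52), (0.57, 0.42)),
    modes=((0.20, 0.60), (0.41, 0.19), (0.05, 0.21)),
    burst_popen=0.32, burst_length_ms=4.24,
    printed_mean_open_ms=0.26,
))
_register(PhenotypeProfile(
    label="a1L300V",
    macro=MacroTargets(0.60, 0.31, 0.17, 0.13, 2.42, 210.0,
                       0.69, 0.19, 0.12, 116.50),
    shut_mix=MixtureTargets((0.11, 1.08, 4.75), (0.05, 0.87, 0.08)),
    open_mix=MixtureTargets((0.20, 0.62), (0.52, 0.48)),
    modes=((0.19, 1.0),),
    burst_popen=0.31, burst_length_ms=27.06,
    printed_mean_open_ms=0.39,
))


def get_profile(label: str) -> PhenotypeProfile:
    try:
        return PROFILES[label]
    except KeyError:
        raise KeyError(
            f"unknown profile {label!r}; available: {sorted(PROFILES)}"
        ) from None
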