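"""Growth-performance algebra for von Bertalanffy growth parameters.

The growth-performance index phi standardises the von Bertalanffy growth
coefficient K (yr^-1) against asymptotic length L_inf (cm total length):

    phi = log10(K) - S_L * log10(L_inf)

where S_L is the slope between log10(L_inf) and log10(K).  Under the
"constant" parameterisation S_L = -(m * b), with m the metabolic (anabolic)
scaling exponent (0.761 on average for fishes) and b the length-weight
regression exponent (3.03 across species).  Changes in phi between two
states can be re-expressed as equivalent changes in K alone (holding L_inf)
or in L_inf alone (holding K):

    K_t / K_{t-1}         = 10 ** (delta_phi)
    L_inf_t / L_inf_{t-1} = 10 ** (-delta_phi / S_L)

All functions here are closed-form; the module also provides the empirical
per-species S_L regression and the table-level attachment used by the
pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean metabolic scaling exponent for fishes (stands in for the anabolic
#: exponent of the von Bertalanffy model).
DEFAULT_M = 0.761
#: Mean length-weight regression exponent across fish species.
DEFAULT_B = 3.03

LENGTH_MEASURES = ("TL", "SL", "FL")
AGING_METHODS = ("otolith", "mark_recapture", "other_rings", "length_frequency", "unknown")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class VBGFParams:
    """Von Bertalanffy growth parameters: L_inf in cm total length, K per year."""

    L_inf: float
    K: float

    def __post_init__(self) -> None:
        if not (self.L_inf > 0 and math.isfinite(self.L_inf)):
            raise ValidationError(f"L_inf must be strictly positive, got {self.L_inf}")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValidationError(f"K must be strictly positive, got {self.K}")


@dataclass(frozen=True)
class LengthConversion:
    """Linear length-length conversion: total length = a + b_len * length."""

    a: float
    b_len: float
    source_measure: str

    #: identity conversion for lengths already in total length
    def __post_init__(self) -> None:
        if self.b_len <= 0:
            raise ValidationError(f"conversion slope must be positive, got {self.b_len}")
        measure = _canonical_measure(self.source_measure)
        object.__setattr__(self, "source_measure", measure)


def _canonical_measure(measure: str) -> str:
    m = measure.strip().upper()
    aliases = {"TOTAL": "TL", "STANDARD": "SL", "FORK": "FL"}
    m = aliases.get(m, m)
    if m not in LENGTH_MEASURES:
        raise ValidationError(f"unknown length measure {measure!r}")
    return m


IDENTITY_CONVERSION = LengthConversion(a=0.0, b_len=1.0, source_measure="TL")


@dataclass(frozen=True)
class SLValue:
    """Slope between log10(L_inf) and log10(K); negative under the constant form."""

    value: float
    origin: str = "constant"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError("S_L must be finite")
        if self.origin not in ("constant", "empirical"):
            raise ValidationError(f"unknown S_L origin {self.origin!r}")


@dataclass(frozen=True)
class GrowthPerformance:
    phi: float
    sl_used: SLValue


@dataclass(frozen=True)
class DeltaPhi:
    """Change in growth performance phi_t - phi_{t-1}."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError("delta phi must be finite")


def convert_to_total_length(length: float, conv: LengthConversion) -> float:
    """Convert a standard/fork length (cm) to total length via TL = a + b * length."""
    if not (length > 0 and math.isfinite(length)):
        raise ValidationError(f"length must be strictly positive, got {length}")
    if conv.source_measure == "TL" and (conv.a, conv.b_len) != (0.0, 1.0):
        # total-length inputs pass through untouched by convention
        return float(length)
    return float(conv.a + conv.b_len * length)


def constant_SL(m: float = DEFAULT_M, b: float = DEFAULT_B) -> SLValue:
    """The constant S_L = -(m * b) from the metabolic and length-weight exponents."""
    if m <= 0 or b <= 0:
        raise ValidationError(f"exponents must be positive, got m={m}, b={b}")
    return SLValue(value=-(m * b), origin="constant")


def compute_phi(p: VBGFParams, sl: SLValue) -> GrowthPerformance:
    """phi = log10 K - S_L * log10 L_inf."""
    phi = math.log10(p.K) - sl.value * math.log10(p.L_inf)
    return GrowthPerformance(phi=phi, sl_used=sl)


def delta_phi(p_t: VBGFParams, p_prev: VBGFParams, sl: SLValue) -> DeltaPhi:
    """phi_t - phi_{t-1} expressed through the two parameter ratios."""
    value = math.log10(p_t.K / p_prev.K) - sl.value * math.log10(p_t.L_inf / p_prev.L_inf)
    return DeltaPhi(value=value)


def K_ratio_from_delta_phi(d: DeltaPhi) -> float:
    """K_t / K_{t-1} implied by a phi change when L_inf is held constant."""
    return 10.0 ** d.value


def Linf_ratio_from_delta_phi(d: DeltaPhi, sl: SLValue) -> float:
    """L_inf_t / L_inf_{t-1} implied by a phi change when K is held constant."""
    if sl.value == 0:
        raise ValidationError("L_inf ratio is undefined for S_L = 0")
    return 10.0 ** (-d.value / sl.value)


def percent_change(ratio: float) -> float:
    """Ratio expressed as a percent change, 100 * (ratio - 1)."""
    return 100.0 * (ratio - 1.0)


def temperature_slope_to_percent(
    beta: float, phi_baseline: float, sl: SLValue | None = None
) -> tuple[float, float]:
    """Percent change in (L_inf, K) per +1 degree C for a log-mean-scale slope beta.

    A slope beta on the log link multiplies the mean growth performance by
    e^beta per degree, so the phi change at baseline phi_0 is
    delta_phi = phi_0 * (e^beta - 1); the equivalent single-parameter
    changes then follow from the ratio identities.
    """
    if sl is None:
        sl = constant_SL()
    if phi_baseline <= 0:
        raise ValidationError("phi baseline must be positive")
    d = DeltaPhi(value=phi_baseline * math.expm1(beta))
    pct_linf = percent_change(Linf_ratio_from_delta_phi(d, sl))
    pct_k = percent_change(K_ratio_from_delta_phi(d))
    return pct_linf, pct_k


# ---------------------------------------------------------------------------
# Empirical S_L
# ---------------------------------------------------------------------------

#: minimum observations per species x aging-method group for an empirical slope
MIN_GROUP_SIZE = 4


def empirical_SL_by_method(
    observations: pd.DataFrame,
    min_group_size: int = MIN_GROUP_SIZE,
) -> dict[tuple[str, str], float]:
    """OLS slope of log10 K on log10 L_inf per (species, aging method) group.

    Only groups with at least ``min_group_size`` rows qualify; groups with
    zero variance in log10 L_inf yield no slope (logged); non-negative
    slopes are returned as-is with a warning.
    """
    required = {"species", "aging_method", "L_inf_cm", "K_per_year"}
    missing = required - set(observations.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")

    slopes: dict[tuple[str, str], float] = {}
    for (species, method), grp in observations.groupby(["species", "aging_method"]):
        if len(grp) < min_group_size:
            continue
        x = np.log10(grp["L_inf_cm"].to_numpy(dtype=float))
        y = np.log10(grp["K_per_year"].to_numpy(dtype=float))
        if np.ptp(x) == 0:
            logger.warning(
                "species %s / method %s: zero variance in log10 L_inf, "
                "falling back to constant S_L",
                species,
                method,
            )
            continue
        slope = float(np.polyfit(x, y, 1)[0])
        if slope >= 0:
            logger.warning(
                "species %s / method %s: non-negative empirical S_L %.3f used as-is",
                species,
                method,
                slope,
            )
        slopes[(str(species), str(method))] = slope
    return slopes


def empirical_SL(
    observations: pd.DataFrame,
    fallback: SLValue | None = None,
    min_group_size: int = MIN_GROUP_SIZE,
) -> dict[str, SLValue]:
    """Per-species empirical S_L from OLS of log10 K on log10 L_inf.

    A species with qualifying groups under several aging methods gets the
    median across its per-method slopes (see :func:`empirical_SL_by_method`
    for the raw per-method values).  Species with no qualifying group fall
    back to the constant S_L.

    Parameters
    ----------
    observations
        Table with columns ``species``, ``aging_method``, ``L_inf_cm``,
        ``K_per_year``.
    """
    if fallback is None:
        fallback = constant_SL()
    per_method = empirical_SL_by_method(observations, min_group_size=min_group_size)
    slopes_by_species: dict[str, list[float]] = {}
    for (species, _method), slope in per_method.items():
        slopes_by_species.setdefault(species, []).append(slope)

    out: dict[str, SLValue] = {}
    for species in observations["species"].unique():
        slopes = slopes_by_species.get(str(species))
        if slopes:
            out[str(species)] = SLValue(value=float(np.median(slopes)), origin="empirical")
        else:
            out[str(species)] = fallback
    return out


# ---------------------------------------------------------------------------
# Table-level attachment
# ---------------------------------------------------------------------------

ConversionTable = Mapping[tuple[str, str, str], tuple[float, float]]
# keyed (level, name, measure) -> (a, b); level in {species, genus, family}


def lookup_conversion(
    table: ConversionTable | None,
    species: str,
    genus: str | None,
    family: str | None,
    measure: str,
) -> LengthConversion | None:
    """Resolve length-conversion coefficients species-first, then genus, then family."""
    measure = _canonical_measure(measure)
    if measure == "TL":
        return IDENTITY_CONVERSION
    if table is None:
        return None
    for level, name in (("species", species), ("genus", genus), ("family", family)):
        if name is None:
            continue
        hit = table.get((level, str(name).strip().lower(), measure))
        if hit is not None:
            return LengthConversion(a=hit[0], b_len=hit[1], source_measure=measure)
    return None


def read_conversion_table(path) -> dict[tuple[str, str, str], tuple[float, float]]:
    """Read a CSV of conversion coefficients with columns level,taxon,measure,a,b."""
    df = pd.read_csv(path)
    table = {}
    for row in df.itertuples(index=False):
        table[(str(row.level), str(row.taxon).strip().lower(), _canonical_measure(str(row.measure)))] = (
            float(row.a),
            float(row.b),
        )
    return table


def attach_growth_performance(
    df: pd.DataFrame,
    sl_mode: str = "constant",
    conversions: ConversionTable | None = None,
) -> pd.DataFrame:
    """Augment an observation table with total-length L_inf, phi, and the S_L used.

    Rows measured in standard or fork length without resolvable conversion
    coefficients are dropped (mirroring exclusion of observations whose
    growth parameters cannot be standardised) and logged.
    """
    if sl_mode not in ("constant", "empirical"):
        raise ValidationError(f"unknown S_L mode {sl_mode!r}")
    df = df.copy()
    const = constant_SL()
    sl_map: dict[str, SLValue] = {}
    if sl_mode == "empirical":
        sl_map = empirical_SL(df, fallback=const)

    linf_tl = np.full(len(df), np.nan)
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        conv = lookup_conversion(
            conversions,
            species=row.species,
            genus=getattr(row, "genus", None),
            family=getattr(row, "family", None),
            measure=row.length_measure,
        )
        if conv is None:
            keep[i] = False
            logger.warning(
                "dropping %s: no length conversion for measure %s", row.species, row.length_measure
            )
            continue
        linf_tl[i] = convert_to_total_length(float(row.L_inf_cm), conv)

    df["L_inf_tl_cm"] = linf_tl
    df = df.loc[keep].copy()

    sls = [sl_map.get(str(s), const) if sl_mode == "empirical" else const for s in df["species"]]
    df["S_L"] = [sl.value for sl in sls]
    df["S_L_origin"] = [sl.origin for sl in sls]
    df["phi"] = [
        compute_phi(VBGFParams(L_inf=linf, K=k), sl).phi
        for linf, k, sl in zip(df["L_inf_tl_cm"], df["K_per_year"], sls)
    ]
    return df
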