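"""Relative Wolbachia titer and the titer-threshold model of thelytoky.

Wolbachia-induced thelytoky turns unfertilized eggs into diploid females.
Two candidate mechanisms differ in how many endosymbiont actions are
involved: a *one-step* model in which diploidization alone suffices for
female development, and a *two-step* model in which diploidization and
feminization are separate titer-dependent events. When the two steps
require different titers, intermediate endosymbiont densities produce
diploid *males* (eggs diploidized but not feminized); when diploid males
never appear across a titer gradient, the data are compatible with either
the one-step model or a two-step model whose thresholds coincide.

Relative titer is quantified by qPCR as twice the Wolbachia gene quantity
(*gssb*) over the host single-copy gene quantity (*ef1a*), the factor two
correcting for the two host gene copies per diploid cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QpcrSample",
    "MechanismModel",
    "MechanismVerdict",
    "DOSE_RESPONSE_COLUMNS",
    "relative_titer",
    "relative_titer_table",
    "dose_response_rates",
    "egg_fate",
    "expected_category_fractions",
    "simulate_dose_response",
    "classify_mechanism",
]

DOSE_RESPONSE_COLUMNS = [
    "dose",
    "n_mothers",
    "n_offspring",
    "n_female",
    "n_male",
    "n_males_tested",
    "n_diploid_males_found",
    "n_flies_emerged",
    "n_flies_unemerged",
]


@dataclass(frozen=True)
class QpcrSample:
    """One female's qPCR measurement, as quantities or cycle thresholds.

    Exactly one of (``gssb_quantity``, ``ef1a_quantity``) or
    (``ct_gssb``, ``ct_ef1a``) must be given. ``efficiency`` is the
    amplification factor per cycle (2.0 = perfect doubling).
    """

    individual_id: str | int
    dose: float = 0.0
    gssb_quantity: float | None = None
    ef1a_quantity: float | None = None
    ct_gssb: float | None = None
    ct_ef1a: float | None = None
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        has_q = self.gssb_quantity is not None or self.ef1a_quantity is not None
        has_ct = self.ct_gssb is not None or self.ct_ef1a is not None
        if has_q == has_ct:
            raise ValueError("give either quantities or Ct values, not both/neither")
        if has_q:
            if self.gssb_quantity is None or self.ef1a_quantity is None:
                raise ValueError("both gssb_quantity and ef1a_quantity required")
            if self.gssb_quantity < 0 or self.ef1a_quantity <= 0:
                raise ValueError("quantities must be positive (ef1a > 0)")
        else:
            if self.ct_gssb is None or self.ct_ef1a is None:
                raise ValueError("both ct_gssb and ct_ef1a required")
            if self.ct_gssb < 0 or self.ct_ef1a < 0:
                raise ValueError("Ct values must be >= 0")
        if self.efficiency <= 1.0:
            raise ValueError("amplification efficiency must exceed 1")


def relative_titer(sample: QpcrSample) -> float:
    """Relative Wolbachia titer: 2 x gssb / ef1a.

    From cycle thresholds: ``2 * efficiency ** (ct_ef1a - ct_gssb)`` —
    lower Ct means more template, so a Wolbachia-rich sample has
    ``ct_gssb < ct_ef1a``.
    """
    if sample.gssb_quantity is not None:
        return 2.0 * sample.gssb_quantity / sample.ef1a_quantity
    return 2.0 * sample.efficiency ** (sample.ct_ef1a - sample.ct_gssb)


def relative_titer_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`relative_titer` to a qPCR CSV table.

    Expects columns ``individual_id, dose`` plus either
    ``gssb_quantity, ef1a_quantity`` or ``ct_gssb, ct_ef1a``
    (optional ``efficiency``). Returns the table with a ``titer`` column.
    """
    out = df.copy()
    titers = []
    for _, row in df.iterrows():
        kwargs = {"individual_id": row["individual_id"], "dose": row.get("dose", 0.0)}
        if "gssb_quantity" in df.columns and pd.notna(row.get("gssb_quantity")):
            kwargs["gssb_quantity"] = float(row["gssb_quantity"])
            kwargs["ef1a_quantity"] = float(row["ef1a_quantity"])
        else:
            kwargs["ct_gssb"] = float(row["ct_gssb"])
            kwargs["ct_ef1a"] = float(row["ct_ef1a"])
        if "efficiency" in df.columns and pd.notna(row.get("efficiency")):
            kwargs["efficiency"] = float(row["efficiency"])
        titers.append(relative_titer(QpcrSample(**kwargs)))
    out["titer"] = titers
    return out


def _logistic_response(titer, threshold: float, slope: float):
    """Non-decreasing logistic in log-titer; slope=inf is a sharp threshold.

    p(titer) = titer**s / (titer**s + threshold**s), so p -> 0 as titer -> 0,
    p(threshold) = 1/2 and p -> 1 at high titer.
    """
    t = np.asarray(titer, dtype=float)
    if np.any(t < 0):
        raise ValueError("titer must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if np.isinf(slope):
        p = np.where(t > threshold, 1.0, np.where(t < threshold, 0.0, 0.5))
    else:
        if slope <= 0:
            raise ValueError("slope must be > 0")
        with np.errstate(divide="ignore"):
            r = (t / threshold) ** slope
        p = r / (1.0 + r)
        p = np.where(np.isinf(r), 1.0, p)
    return p if p.shape else float(p)


@dataclass(frozen=True)
class MechanismModel:
    """Titer-dependent egg-fate model.

    ``p_dip(titer)`` is the diploidization probability and, for the
    two-step variant, ``p_fem(titer)`` the feminization probability of a
    diploidized egg; both are non-decreasing logistics in log-titer with a
    threshold (titer at half response) and a slope (``float('inf')`` gives
    a sharp threshold). The one-step variant feminizes every diploidized
    egg and ignores the feminization parameters.
    """

    variant: str
    t_dip: float
    s_dip: float = np.inf
    t_fem: float | None = None
    s_fem: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("one_step", "two_step"):
            raise ValueError("variant must be 'one_step' or 'two_step'")
        if self.variant == "two_step" and self.t_fem is None:
            raise ValueError("two_step requires a feminization threshold t_fem")

    def p_dip(self, titer):
        return _logistic_response(titer, self.t_dip, self.s_dip)

    def p_fem(self, titer):
        if self.variant == "one_step":
            return np.ones_like(np.asarray(titer, dtype=float)) if np.ndim(titer) else 1.0
        s = self.s_fem if self.s_fem is not None else self.s_dip
        return _logistic_response(titer, self.t_fem, s)


def expected_category_fractions(
    titer: float, model: MechanismModel
) -> tuple[float, float, float]:
    """(p_haploid_male, p_diploid_male, p_diploid_female) at a given titer."""
    pd_ = float(model.p_dip(titer))
    pf = float(model.p_fem(titer))
    p_hap = 1.0 - pd_
    p_dip_male = pd_ * (1.0 - pf)
    return p_hap, p_dip_male, pd_ * pf


def egg_fate(titer: float, model: MechanismModel, rng: np.random.Generator) -> str:
    """Fate of one unfertilized egg: 'haploid_male', 'diploid_male' or 'diploid_female'."""
    if rng.random() >= model.p_dip(titer):
        return "haploid_male"
    if rng.random() < model.p_fem(titer):
        return "diploid_female"
    return "diploid_male"


def simulate_dose_response(
    model: MechanismModel,
    dose_titer_map: Mapping[float, Callable[[np.random.Generator], float] | float],
    clutch_model: Callable[[np.random.Generator], int] | int,
    n_mothers: int,
    seed: int,
    test_all_males: bool = True,
    fly_rate: float = 10.0,
    unemerged_rate: float = 0.5,
) -> pd.DataFrame:
    """Simulate an antibiotic dose-response table of thelytokous broods.

    Per mother at each dose, a titer is drawn from that dose's distribution
    (a callable taking the generator, or a fixed float), a clutch size is
    drawn, and each unfertilized egg's fate follows :func:`egg_fate`'s
    closed-form category probabilities (multinomial draw). Emerged and
    non-emerged host-fly counts are Poisson noise, independent of treatment,
    matching the absence of a viability effect. With ``test_all_males``
    every male is scored for ploidy; otherwise roughly half are.
    """
    if not dose_titer_map:
        raise ValueError("dose_titer_map must contain at least one dose")
    rng = np.random.default_rng(seed)
    rows = []
    for dose, titer_source in sorted(dose_titer_map.items()):
        n_off = n_fem = n_male = n_tested = n_dip_found = 0
        flies = unemerged = 0
        for _ in range(n_mothers):
            titer = float(titer_source(rng)) if callable(titer_source) else float(titer_source)
            clutch = int(clutch_model(rng)) if callable(clutch_model) else int(clutch_model)
            p = expected_category_fractions(titer, model)
            n_hap, n_dip_m, n_dip_f = rng.multinomial(clutch, p)
            n_off += clutch
            n_fem += n_dip_f
            males = n_hap + n_dip_m
            n_male += males
            if test_all_males:
                tested_dip = n_dip_m
                tested = males
            else:
                tested = int(rng.binomial(males, 0.5))
                tested_dip = int(rng.hypergeometric(n_dip_m, n_hap, tested)) if tested else 0
            n_tested += tested
            n_dip_found += tested_dip
            flies += int(rng.poisson(fly_rate))
            unemerged += int(rng.poisson(unemerged_rate))
        rows.append(
            {
                "dose": dose,
                "n_mothers": n_mothers,
                "n_offspring": n_off,
                "n_female": n_fem,
                "n_male": n_male,
                "n_males_tested": n_tested,
                "n_diploid_males_found": n_dip_found,
                "n_flies_emerged": flies,
                "n_flies_unemerged": unemerged,
            }
        )
    return pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)


def dose_response_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Add male-proportion and diploid-detection columns to a dose table."""
    out = table.copy()
    out["prop_male"] = out["n_male"] / out["n_offspring"].replace(0, np.nan)
    return out


@dataclass(frozen=True)
class MechanismVerdict:
    """Outcome of the mechanism classification.

    ``verdict`` is ``two_step_separated`` when diploid males were found,
    ``one_step_or_coincident`` when zero diploid males were found and the
    testing effort suffices to reject the separated two-step alternative,
    and ``inconclusive`` otherwise. ``zero_diploid_probability`` is the
    probability of the observed all-haploid outcome under the alternative.
    """

    verdict: str
    zero_diploid_probability: float
    n_males_tested_mixed: int
    n_diploid_males_found: int
    alpha: float
    d_alternative: float


def classify_mechanism(
    table: pd.DataFrame, alpha: float = 0.05, d_alternative: float = 0.5
) -> MechanismVerdict:
    """Classify the thelytoky mechanism from a dose-response table.

    Diploid males at any dose directly demonstrate separated diploidization
    and feminization thresholds. With zero diploid males, the separated
    two-step alternative is assessed through the males tested in mixed-sex
    dose rows (under a sharp separated alternative those broods straddle
    the feminization threshold and carry diploid males at expected fraction
    ``d_alternative``): if the all-haploid outcome has probability
    ``<= alpha`` under that alternative, the data support one-step
    induction or a two-step mechanism with coincident thresholds — the two
    cannot be told apart by titer manipulation alone.
    """
    if table.empty:
        raise ValueError("dose-response table is empty")
    if int(table["n_males_tested"].sum()) == 0:
        raise ValueError("no males tested for ploidy in table")
    n_dip = int(table["n_diploid_males_found"].sum())
    n_female = table["n_female"] if "n_female" in table.columns else (
        table["n_offspring"] - table["n_male"]
    )
    mixed = (table["n_male"] > 0) & (n_female > 0)
    n_tested_mixed = int(table.loc[mixed, "n_males_tested"].sum())
    p_zero = zero_prob = (1.0 - d_alternative) ** n_tested_mixed
    if n_dip > 0:
        verdict = "two_step_separated"
    elif p_zero <= alpha:
        verdict = "one_step_or_coincident"
    else:
        verdict = "inconclusive"
    return MechanismVerdict(
        verdict=verdict,
        zero_diploid_probability=zero_prob,
        n_males_tested_mixed=n_tested_mixed,
        n_diploid_males_found=n_dip,
        alpha=alpha,
        d_alternative=d_alternative,
    )
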