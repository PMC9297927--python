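"""Synthetic-data generators emulating the experiments' raw tables.

The study's per-brood records and qPCR tables are not deposited, so these
generators produce tables with the statistical structure the analyses
assume: per-family brood records across inbreeding generations with an
unmated-female fraction, overdispersed brood sizes (negative binomial) and
beta-distributed fertilization proportions, optional inbreeding-depression
mortality confined to diploid females (the dead females turning up as
non-emerged host pupae, as in the dissection data), and dose-response and
qPCR tables built on the titer-threshold model. Embedding a true CSD
configuration lets the detection pipeline be exercised against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .broods import BROOD_COLUMNS
from .crosses import CrossScheme, CrossStep
from .genetics import CsdParams, Individual, Sex
from .pedigree import BroodModel, Extinct, init_f0, next_pair, produce_brood
from .titer import MechanismModel, simulate_dose_response

__all__ = [
    "ExperimentConfig",
    "generate_inbreeding_dataset",
    "generate_qpcr_dataset",
    "generate_dose_response_dataset",
    "write_with_manifest",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a synthetic inbreeding experiment.

    ``n_families`` lineages are followed per group (inbred and control);
    each contributes at most one brood record per generation. Control
    lineages are re-outcrossed to an unrelated stock male every generation.
    ``p_unmated`` is the chance a generation's record comes from an unmated
    (all-male-brood) female. ``female_survival_multiplier`` < 1 applies
    geometric inbreeding-depression mortality to diploid females of inbred
    generation g (survival ``multiplier ** g``); dead females are counted
    as non-emerged host pupae and sexed in the dissection columns.
    """

    scheme: CrossScheme = field(default_factory=lambda: CrossScheme.preset("heterotoma"))
    csd: CsdParams = field(default_factory=lambda: CsdParams(n_loci=1, csd_enabled=False))
    n_families: int = 30
    p_unmated: float | Mapping[str, float] = 0.5
    brood_mean: float = 20.0
    brood_dispersion: float = 5.0
    fertilization_beta_a: float = 6.5
    fertilization_beta_b: float = 3.5
    female_survival_multiplier: float = 1.0
    baseline_death: float = 0.05
    fly_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.female_survival_multiplier <= 1.0:
            raise ValueError("female_survival_multiplier must be in (0, 1]")
        if not 0.0 <= self.baseline_death < 1.0:
            raise ValueError("baseline_death must be in [0, 1)")
        for g, p in self._p_unmated_by_group().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_unmated[{g}] must be in [0, 1]")

    def _p_unmated_by_group(self) -> dict[str, float]:
        if isinstance(self.p_unmated, Mapping):
            return {g: float(self.p_unmated.get(g, 0.0)) for g in ("inbred", "control")}
        return {"inbred": float(self.p_unmated), "control": float(self.p_unmated)}

    def brood_model(self) -> BroodModel:
        return BroodModel.parametric(
            mean=self.brood_mean,
            dispersion=self.brood_dispersion,
            beta_a=self.fertilization_beta_a,
            beta_b=self.fertilization_beta_b,
        )

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = {"label": self.scheme.label, "steps": [s.value for s in self.scheme.steps]}
        d["csd"] = dataclasses.asdict(self.csd)
        if isinstance(self.p_unmated, Mapping):
            d["p_unmated"] = dict(self.p_unmated)
        return d


def _record_from_brood(
    mother_id: str,
    group: str,
    label: str,
    brood: Sequence[Individual],
    config: ExperimentConfig,
    depression_generation: int,
    rng: np.random.Generator,
) -> tuple[dict, list[Individual]]:
    """Turn a simulated brood into a brood record; returns survivors too."""
    survival = config.female_survival_multiplier**depression_generation
    n_f = n_m = n_dip = dead_f = dead_m = 0
    survivors: list[Individual] = []
    for ind in brood:
        dies = rng.random() < config.baseline_death
        if ind.sex is Sex.FEMALE:
            if dies or rng.random() > survival:
                dead_f += 1
            else:
                n_f += 1
                survivors.append(ind)
        else:
            if ind.sex is Sex.DIPLOID_MALE and not config.csd.diploid_male_viable:
                dies = True
            if dies:
                dead_m += 1
            else:
                n_m += 1
                if ind.sex is Sex.DIPLOID_MALE:
                    n_dip += 1
                survivors.append(ind)
    flies = int(rng.poisson(config.fly_rate))
    unemerged = dead_f + dead_m
    record = {
        "mother_id": mother_id,
        "group": group,
        "generation": label,
        "n_female_adults": n_f,
        "n_male_adults": n_m,
        "n_flies_emerged": flies,
        "n_fly_pupae_unemerged": unemerged,
        "n_hosts": n_f + n_m + flies + unemerged,
        "n_dead_wasps_female": dead_f,
        "n_dead_wasps_male": dead_m,
        "n_diploid_male_adults": n_dip,
    }
    return record, survivors


def generate_inbreeding_dataset(config: ExperimentConfig) -> pd.DataFrame:
    """Generate a per-brood record table for inbred and control groups.

    Each family is a lineage run through the scheme (control lineages
    replace every post-F0 cross by an outcross to a fresh stock male).
    Unmated draws are recorded as all-male broods — the record emulates a
    sister female that failed to mate — while the lineage itself continues
    from the mated brood. Lineages end early when a brood lacks the sexes
    needed for the next cross. The ``n_diploid_male_adults`` column is the
    generator's hidden truth channel, standing in for a ploidy assay.
    """
    rng = np.random.default_rng(config.seed)
    brood_model = config.brood_model()
    labels = config.scheme.generation_labels()
    p_unmated = config._p_unmated_by_group()
    rows: list[dict] = []
    for group in ("inbred", "control"):
        for fam in range(config.n_families):
            mother, father = init_f0(config.csd)
            for gi, step in enumerate(config.scheme.steps):
                brood = produce_brood(mother, father, brood_model, config.csd, rng)
                depression_gen = gi if group == "inbred" else 0
                record, survivors = _record_from_brood(
                    f"{group}-{fam}-{labels[gi]}",
                    group,
                    labels[gi],
                    brood,
                    config,
                    depression_gen,
                    rng,
                )
                if rng.random() < p_unmated[group]:
                    # Record an unmated sister's all-male brood instead.
                    size, _ = brood_model.sample(rng)
                    virgin_brood = (
                        produce_brood(
                            mother,
                            father,
                            BroodModel.empirical([(size, 0.0)]),
                            config.csd,
                            rng,
                        )
                        if size
                        else []
                    )
                    record, _ = _record_from_brood(
                        f"{group}-{fam}-{labels[gi]}-unmated",
                        group,
                        labels[gi],
                        virgin_brood,
                        config,
                        depression_gen,
                        rng,
                    )
                rows.append(record)
                if gi + 1 == len(config.scheme.steps):
                    break
                nxt = (
                    config.scheme.steps[gi + 1]
                    if group == "inbred"
                    else CrossStep.OUTCROSS
                )
                try:
                    if nxt is CrossStep.OUTCROSS:
                        females = [i for i in survivors if i.sex is Sex.FEMALE]
                        if not females:
                            raise Extinct("no surviving females")
                        mother = females[rng.integers(len(females))]
                        from .pedigree import _novel_stock_male

                        father = _novel_stock_male(config.csd, gi + 1)
                    else:
                        mother, father = next_pair(survivors, nxt, mother, rng)
                except Extinct:
                    break
    return pd.DataFrame(rows, columns=BROOD_COLUMNS + ["n_diploid_male_adults"])


def generate_qpcr_dataset(
    doses: Sequence[float],
    n_per_dose: int = 10,
    plateau: float = 6.2,
    d50: float = 0.2,
    hill: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate qPCR samples along a decreasing titer dose-response curve.

    The mean relative titer follows ``plateau / (1 + (dose / d50) ** hill)``
    (controls at dose 0 sit on the plateau) with log-normal noise of the
    given log-scale standard deviation. Quantities are emitted with the
    host gene as the unit, so titer recomputes exactly as 2 x gssb / ef1a.
    """
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        mean = plateau / (1.0 + (dose / d50) ** hill) if dose > 0 else plateau
        for j in range(n_per_dose):
            titer = mean * float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else mean
            rows.append(
                {
                    "individual_id": f"d{dose}-{j}",
                    "dose": dose,
                    "gssb_quantity": titer / 2.0,
                    "ef1a_quantity": 1.0,
                }
            )
    return pd.DataFrame(rows)


def generate_dose_response_dataset(
    model: MechanismModel,
    doses: Sequence[float] = (0.0, 0.016, 0.031, 0.063, 0.125, 0.25, 0.5, 1.0),
    n_mothers: int = 5,
    clutch_mean: float = 20.0,
    clutch_dispersion: float = 5.0,
    plateau: float = 6.2,
    d50: float = 0.2,
    hill: float = 3.0,
    titer_noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a dose-response table under a given thelytoky mechanism.

    Per-dose titers follow the same decreasing curve as
    :func:`generate_qpcr_dataset`; clutch sizes are negative binomial.
    """
    rng_titer_base = np.random.default_rng  # titer noise uses the shared rng below

    def titer_source(dose: float):
        mean = plateau / (1.0 + (dose / d50) ** hill) if dose > 0 else plateau

        def draw(rng: np.random.Generator) -> float:
            if titer_noise_sd:
                return mean * float(np.exp(rng.normal(0.0, titer_noise_sd)))
            return mean

        return draw

    p = clutch_dispersion / (clutch_dispersion + clutch_mean)

    def clutch(rng: np.random.Generator) -> int:
        return int(rng.negative_binomial(clutch_dispersion, p))

    dose_titer_map = {float(d): titer_source(float(d)) for d in doses}
    return simulate_dose_response(
        model, dose_titer_map, clutch, n_mothers=n_mothers, seed=seed
    )


def write_with_manifest(
    df: pd.DataFrame, path: str | Path, parameters: Mapping, seed: int
) -> Path:
    """Write a CSV plus a JSON manifest of the generating parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest = {"output": path.name, "seed": seed, "parameters": dict(parameters)}
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
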