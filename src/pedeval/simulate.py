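"""Synthetic herdbook generator.

Generates multi-generation pedigrees and repeated-record phenotypes with the
variance structure of the repeatability animal model

    y = Xb + Za + W pe + S d + e,

with a ~ N(0, A sigma_a2) simulated by gene dropping (founders drawn
independently, descendants as parent average plus Mendelian sampling),
pe ~ N(0, I sigma_pe2) one draw per cow, d ~ N(0, I sigma_cg2) one draw per
herd-year contemporary group, and e ~ N(0, I sigma_e2) per record.

The defaults emulate the structure of a Brazilian Dairy Gir type-trait
herdbook: cows evaluated one to four times (most once), herd-year
contemporary groups, two evaluation seasons (dry/rainy, derived from a
simulated month), a small evaluator pool per herd, a diet factor, and dam
age at evaluation of 1820 +/- 788 days entering as a recentred linear +
quadratic covariate.  Score traits are produced by cutting a latent Gaussian
liability at 8 ordered thresholds into a 1-9 scale.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable, mendelian_sampling_variances, topological_sort

#: Dam age at evaluation (days): mean and SD emulated by the generator.
DAM_AGE_MEAN = 1820.0
DAM_AGE_SD = 788.0


@dataclass(frozen=True)
class FactorConfig:
    """A fixed environmental factor: number of levels and effect range.

    Level effects are drawn once per simulation, uniformly on
    ``[-effect_range/2, +effect_range/2]`` (trait units).
    """

    levels: int
    effect_range: float


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic herdbook.

    Variances are in trait units squared.  ``records_per_cow`` are the
    probabilities of a cow having 1, 2, 3 or 4 evaluations; the default
    (0.78, 0.10, 0.07, 0.05) reproduces a herdbook where ~78% of cows are
    evaluated once and the mean is ~1.4 records per cow.
    """

    n_founders: int = 120
    n_generations: int = 3
    n_offspring: int = 400           # per generation
    sire_fraction: float = 0.10      # fraction of each cohort that are males
    n_herds: int = 8
    years: tuple = (2000, 2012)
    evaluators_per_herd: int = 2
    records_per_cow: tuple = (0.78, 0.10, 0.07, 0.05)
    sigma_a2: float = 8.5
    sigma_pe2: float = 5.0
    sigma_cg2: float = 3.3
    sigma_e2: float = 3.5
    trait_mean: float = 0.0
    fixed_effects: dict = field(default_factory=lambda: {
        "season": FactorConfig(2, 2.0),
        "evaluator": FactorConfig(0, 1.5),   # 0 -> n_herds * evaluators_per_herd
        "diet": FactorConfig(3, 1.5),
    })
    dam_age_coeffs: tuple = (2.0e-3, -5.0e-7)   # linear, quadratic (per day)
    trait: str = "trait"
    trait_scale: str = "linear"                 # "linear" | "ordinal-9"
    thresholds: tuple = None                    # 8 cutpoints; None -> default grid
    residual_law: str = "gaussian"              # "gaussian" | "logistic" (ordinal)
    seed: int = 2024

    def __post_init__(self):
        for name in ("sigma_a2", "sigma_pe2", "sigma_cg2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        p = np.asarray(self.records_per_cow, dtype=float)
        if len(p) != 4 or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("records_per_cow must be 4 probabilities summing to 1")
        if self.trait_scale not in ("linear", "ordinal-9"):
            raise ValueError("trait_scale must be 'linear' or 'ordinal-9'")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if len(t) != 8 or np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be 8 strictly increasing cutpoints")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.residual_law not in ("gaussian", "logistic"):
            raise ValueError("residual_law must be 'gaussian' or 'logistic'")

    def default_thresholds(self) -> np.ndarray:
        """Equally spaced cutpoints on the latent scale, shifted left so the
        modal category sits at 3-4 (the right-skewed profile typical of
        milking scores)."""
        sigma_p = np.sqrt(
            self.sigma_a2 + self.sigma_pe2 + self.sigma_cg2 + self.sigma_e2
        )
        return self.trait_mean + (np.arange(1, 9) - 3.0) * 0.55 * sigma_p


@dataclass
class SimulatedDataset:
    """Generated pedigree, phenotype records and the underlying truth."""

    pedigree: PedigreeTable
    records: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        from .pedigree import write_pedigree_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree_csv(self.pedigree, outdir / "pedigree.csv")
        self.records.to_csv(outdir / "phenotypes.csv", index=False)
        truth = pd.DataFrame({
            "animal": list(self.pedigree.ids),
            "breeding_value": self.truth["breeding_values"],
        })
        truth.to_csv(outdir / "truth.csv", index=False)


def _animal_id(i: int) -> str:
    return f"A{i + 1:06d}"


def simulate_pedigree(config: SimulationConfig, rng=None):
    """Multi-generation pedigree; parents drawn from the previous cohort.

    Returns ``(pedigree, sex, generation)`` where sex is a boolean array
    (True = male) and generation an int array, both in pedigree order.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_male0 = max(2, int(round(config.n_founders * config.sire_fraction)))
    ids, sire, dam, sex, gen = [], [], [], [], []
    for i in range(config.n_founders):
        ids.append(_animal_id(i))
        sire.append(-1)
        dam.append(-1)
        sex.append(i < n_male0)
        gen.append(0)
    for g in range(1, config.n_generations + 1):
        prev = [i for i in range(len(ids)) if gen[i] == g - 1]
        males = [i for i in prev if sex[i]]
        females = [i for i in prev if not sex[i]]
        if not males or not females:
            raise ValueError(
                f"cannot breed generation {g}: no {'sires' if not males else 'dams'}"
            )
        n_male = max(2, int(round(config.n_offspring * config.sire_fraction)))
        for k in range(config.n_offspring):
            i = len(ids)
            ids.append(_animal_id(i))
            sire.append(int(rng.choice(males)))
            dam.append(int(rng.choice(females)))
            sex.append(k < n_male)
            gen.append(g)
    ped = PedigreeTable(
        ids=tuple(ids),
        sire=np.asarray(sire, dtype=np.int64),
        dam=np.asarray(dam, dtype=np.int64),
    )
    return ped, np.asarray(sex, dtype=bool), np.asarray(gen, dtype=np.int64)


def simulate_breeding_values(pedigree: PedigreeTable, sigma_a2: float, seed=None,
                             rng=None) -> np.ndarray:
    """Gene-drop breeding values with Var(a) = A sigma_a2.

    Founders ~ N(0, sigma_a2); non-founders are the parent average plus a
    Mendelian-sampling deviation with variance sigma_a2 * d_i, where d_i
    accounts for known parents and their inbreeding.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ped = pedigree if pedigree.is_sorted() else topological_sort(pedigree)
    n = len(ped)
    if sigma_a2 == 0:
        return np.zeros(n)
    d = mendelian_sampling_variances(ped)
    a = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        mid = 0.0
        if ped.sire[i] >= 0:
            mid += 0.5 * a[ped.sire[i]]
        if ped.dam[i] >= 0:
            mid += 0.5 * a[ped.dam[i]]
        a[i] = mid + z[i] * np.sqrt(sigma_a2 * d[i])
    return a


def simulate_records(pedigree=None, config: SimulationConfig = None,
                     sex=None, generation=None) -> SimulatedDataset:
    """Generate the phenotype file (and truth) for a simulated herdbook.

    If ``pedigree`` is None it is simulated from the config.  Recorded cows
    are the females of generations >= 1; founders remain unrecorded
    ancestors so that parents without records still receive EBVs downstream.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    if pedigree is None:
        pedigree, sex, generation = simulate_pedigree(config, rng)
    elif sex is None or generation is None:
        raise ValueError("sex and generation arrays required with an explicit pedigree")

    n = len(pedigree)
    a = simulate_breeding_values(pedigree, config.sigma_a2, rng=rng)

    cows = np.flatnonzero((~sex) & (generation >= 1))
    pe = rng.standard_normal(n) * np.sqrt(config.sigma_pe2)

    # fixed-effect level values
    fx = dict(config.fixed_effects)
    n_eval = fx["evaluator"].levels or config.n_herds * config.evaluators_per_herd
    effects = {}
    for name, fc in fx.items():
        levels = n_eval if name == "evaluator" else fc.levels
        effects[name] = rng.uniform(-fc.effect_range / 2, fc.effect_range / 2, levels)

    # herd structure: cows stay in one herd; evaluators pooled per herd
    herd_of_cow = rng.integers(0, config.n_herds, len(cows))
    eval_pool = np.arange(n_eval) % config.n_herds   # evaluator -> herd
    y0, y1 = config.years
    n_rec_choices = rng.choice(4, size=len(cows), p=list(config.records_per_cow)) + 1

    L, Q = config.dam_age_coeffs
    thr = (np.asarray(config.thresholds, dtype=float)
           if config.thresholds is not None else config.default_thresholds())

    rows = []
    cg_effects = {}
    for ci, cow in enumerate(cows):
        herd = int(herd_of_cow[ci])
        herd_evals = np.flatnonzero(eval_pool == herd)
        if herd_evals.size == 0:
            herd_evals = np.arange(n_eval)
        start_year = int(rng.integers(y0, y1 + 1))
        for r in range(int(n_rec_choices[ci])):
            year = min(start_year + r, y1)
            month = int(rng.integers(1, 13))
            season = 0 if 4 <= month <= 9 else 1     # dry vs rainy
            evaluator = int(rng.choice(herd_evals))
            diet = int(rng.integers(0, fx["diet"].levels))
            dam_age = float(rng.uniform(DAM_AGE_MEAN - 2 * DAM_AGE_SD,
                                        DAM_AGE_MEAN + 2 * DAM_AGE_SD))
            cg = (herd, year)
            if cg not in cg_effects:
                cg_effects[cg] = rng.standard_normal() * np.sqrt(config.sigma_cg2)
            age_c = dam_age - DAM_AGE_MEAN
            if config.residual_law == "logistic":
                # logistic residual scaled to variance sigma_e2 (an ordinal
                # trait generated this way follows the cumulative-logit
                # liability model exactly when sigma_e2 = pi^2/3)
                u = rng.uniform(1e-12, 1 - 1e-12)
                resid = np.log(u / (1 - u)) * np.sqrt(config.sigma_e2 / (np.pi ** 2 / 3))
            else:
                resid = rng.standard_normal() * np.sqrt(config.sigma_e2)
            latent = (config.trait_mean
                      + effects["season"][season]
                      + effects["evaluator"][evaluator]
                      + effects["diet"][diet]
                      + L * age_c + Q * age_c ** 2
                      + a[cow] + pe[cow] + cg_effects[cg]
                      + resid)
            if config.trait_scale == "ordinal-9":
                value = float(1 + np.searchsorted(thr, latent))
            else:
                value = latent
            rows.append({
                "cow": pedigree.ids[cow],
                "herd": f"H{herd + 1:02d}",
                "year": year,
                "season": "dry" if season == 0 else "rainy",
                "evaluator": f"E{evaluator + 1:02d}",
                "diet": f"D{diet + 1}",
                "dam_age": round(dam_age, 1),
                "trait": config.trait,
                "value": value,
            })
    records = pd.DataFrame(rows)
    truth = {
        "breeding_values": a,
        "permanent_environment": pe,
        "cg_effects": cg_effects,
        "fixed_effects": effects,
        "sex": sex,
        "generation": generation,
        "thresholds": thr if config.trait_scale == "ordinal-9" else None,
    }
    return SimulatedDataset(pedigree=pedigree, records=records, truth=truth,
                            config=config)
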