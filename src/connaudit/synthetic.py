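"""Seeded synthetic cohorts with controllable confound structure.

The generator emulates the statistical skeleton of a two-ancestry
developmental cohort:

* two groups A and B (B with proportion ``prop_b``);
* a set of connectivity edges ``race_edges`` whose Fisher-z values are
  shifted by ``edge_effect`` (delta) in group B, back-transformed to r —
  the "race signal in FC";
* an achievement-like score with group-dependent means (the confounded
  path) and, in the ``direct`` / ``mixed`` scenarios, a genuine linear
  dependence on the ``direct_edges`` (the causal path);
* SNP dosages drawn Binomial(2, q_g) with group allele frequencies q_g
  following the Balding-Nichols model: Beta(q(1-F)/F, (1-q)(1-F)/F)
  around an ancestral frequency q with divergence parameter F (FST);
* age and sex independent of the score by construction.

Scenarios
---------
``confound``
    Score depends on group only (``score_effect`` forced to 0): any
    whole-cohort FC-to-score prediction works purely through group.
``direct``
    Score additionally depends linearly on the ``direct_edges``; the
    signal survives within-group stratification.
``mixed``
    Both paths active.
``null``
    No edge effect, equal score means: end-to-end type-I check.

All randomness flows from a single seed through a fixed substream order
(structure, group labels, edges per task, score noise, SNP dosages, SNP
missingness, age, sex, parental education), so adding a modality never
perturbs earlier draws and identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, ConnectivitySet, PhenotypeTable, SNPDosageMatrix
from .connectivity import TimeseriesMatrix
from .edges import EdgeIndex, num_edges
from .exceptions import SpecError

__all__ = [
    "SyntheticSpec",
    "Structure",
    "resolve_structure",
    "generate_cohort",
    "generate_timeseries",
    "plant_snp_overlap",
]

SCENARIOS = ("confound", "direct", "mixed", "null")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a synthetic cohort.

    Defaults encode the audit's reference conditions: a 600-subject,
    20-parcel cohort with a 0.3 Fisher-z group effect on 40 of 190 edges,
    a -0.8 standardized-score gap between groups (means 102 vs 90 at
    sd 15, the WRAT-like scale), and 200 SNPs at FST 0.1 with 10%
    missing genotypes.  ``prop_b`` = 0.445 mirrors a roughly 55/45
    two-ancestry split.
    """

    n: int = 600
    p: int = 20
    prop_b: float = 0.445
    scenario: str = "confound"
    # connectivity effects (Fisher-z scale)
    edge_effect: float = 0.3  # delta, added to race_edges in group B
    n_race_edges: int = 40
    n_direct_edges: int = 20
    race_edges: tuple[int, ...] | None = None
    direct_edges: tuple[int, ...] | None = None
    baseline_z: float = 0.3
    sigma_z: float = 0.2
    tasks: tuple[str, ...] = ("rest",)
    # score model (WRAT-like scale: null RMSE ~ 15)
    score_mean_a: float = 102.0
    score_mean_b: float = 90.0
    score_sd: float = 15.0
    score_effect: float | None = None  # beta; None -> auto in direct/mixed
    # SNP model
    n_snps: int = 200
    fst: float = 0.1
    freq_range: tuple[float, float] = (0.1, 0.9)
    snp_missing_rate: float = 0.1
    snp_race_ids: tuple[int, ...] = ()
    snp_score_ids: tuple[int, ...] = ()
    snp_score_effect: float = 30.0  # gamma, score units per centered dosage
    snp_plant_divergence: float = 0.25  # fixed +/- frequency shift for snp_race_ids
    # demographics
    age_range_months: tuple[int, int] = (96, 276)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SpecError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.prop_b < 1.0:
            raise SpecError("group proportion must be in (0, 1)")
        if self.n < 2 or self.p < 2:
            raise SpecError("need n >= 2 subjects and p >= 2 parcels")
        if self.sigma_z <= 0 or self.score_sd <= 0:
            raise SpecError("noise scales must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise SpecError("FST must be in [0, 1)")
        m = num_edges(self.p)
        for name, edges, count in (
            ("race_edges", self.race_edges, self.n_race_edges),
            ("direct_edges", self.direct_edges, self.n_direct_edges),
        ):
            if edges is not None:
                if any(not 0 <= e < m for e in edges):
                    raise SpecError(f"{name} outside edge range 0..{m - 1}")
            elif count > m:
                raise SpecError(f"n_{name}={count} exceeds m={m}")
        for ids in (self.snp_race_ids, self.snp_score_ids):
            if any(not 0 <= j < self.n_snps for j in ids):
                raise SpecError("planted SNP ids outside 0..n_snps-1")
        if self.scenario == "confound" and self.score_effect not in (None, 0, 0.0):
            raise SpecError("scenario 'confound' requires score_effect = 0")
        if self.scenario == "null":
            if self.score_effect not in (None, 0, 0.0):
                raise SpecError("scenario 'null' requires score_effect = 0")
            # null forces: no edge effect, equal score means
            object.__setattr__(self, "edge_effect", 0.0)
            object.__setattr__(self, "score_mean_b", self.score_mean_a)

    @property
    def m(self) -> int:
        return num_edges(self.p)

    def effective_score_effect(self) -> float:
        """Resolved beta: 0 outside direct/mixed; auto-calibrated if unset.

        The auto value makes the direct-path signal variance equal the
        score noise variance (within-group R^2 of 0.5):
        beta = score_sd / (sigma_z * sqrt(n_direct_edges)).
        """
        if self.scenario in ("confound", "null"):
            return 0.0
        if self.score_effect is not None:
            return float(self.score_effect)
        k = max(1, len(self.direct_edges) if self.direct_edges is not None else self.n_direct_edges)
        return self.score_sd / (self.sigma_z * np.sqrt(k))


@dataclass(frozen=True)
class Structure:
    """Deterministically resolved planted structure of a spec + seed."""

    race_edges: np.ndarray
    direct_edges: np.ndarray
    q_ancestral: np.ndarray
    q_group_a: np.ndarray
    q_group_b: np.ndarray


def _substreams(spec: SyntheticSpec) -> list[np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(9)
    return [np.random.default_rng(c) for c in children]


def resolve_structure(spec: SyntheticSpec) -> Structure:
    """Resolve which edges/SNP frequencies carry planted effects.

    Drawn from the first substream only, so the structure is identical to
    the one :func:`generate_cohort` uses for the same spec.
    """
    rng = _substreams(spec)[0]
    m = spec.m
    if spec.race_edges is not None:
        race = np.array(sorted(spec.race_edges), dtype=int)
    else:
        race = np.sort(rng.choice(m, size=spec.n_race_edges, replace=False))
    if spec.direct_edges is not None:
        direct = np.array(sorted(spec.direct_edges), dtype=int)
    else:
        pool = np.setdiff1d(np.arange(m), race)
        if len(pool) < spec.n_direct_edges:
            raise SpecError("not enough edges left for a disjoint direct set")
        direct = np.sort(rng.choice(pool, size=spec.n_direct_edges, replace=False))

    lo, hi = spec.freq_range
    q_anc = rng.uniform(lo, hi, size=spec.n_snps)
    q_a = np.empty(spec.n_snps)
    q_b = np.empty(spec.n_snps)
    planted = np.zeros(spec.n_snps, dtype=bool)
    planted[list(spec.snp_race_ids)] = True
    for j in range(spec.n_snps):
        q = q_anc[j]
        if planted[j]:
            # reinforcing direction: group A (higher score mean) gets the
            # higher frequency, so divergence and any direct SNP effect
            # push the SNP-score correlation the same way
            q_a[j] = min(q + spec.snp_plant_divergence, 0.99)
            q_b[j] = max(q - spec.snp_plant_divergence, 0.01)
        elif spec.fst > 0:
            a = q * (1 - spec.fst) / spec.fst
            b = (1 - q) * (1 - spec.fst) / spec.fst
            q_a[j] = rng.beta(a, b)
            q_b[j] = rng.beta(a, b)
        else:
            q_a[j] = q_b[j] = q
    return Structure(race, direct, q_anc, q_a, q_b)


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate a fully aligned synthetic :class:`~connaudit.cohort.Cohort`.

    Phenotype columns: ``race`` ("A"/"B"), ``race_code`` (0/1, B = 1),
    ``sex`` (0/1), ``age_months``, ``wrat`` (the achievement-like score),
    ``mother_education`` and ``father_education`` (years; father's has
    planted missingness).  Connectivity values are stored as Pearson r
    (tanh of the generated Fisher-z values).
    """
    (
        _rng_structure,
        rng_group,
        rng_edges,
        rng_score,
        rng_snp,
        rng_miss,
        rng_age,
        rng_sex,
        rng_edu,
    ) = _substreams(spec)
    structure = resolve_structure(spec)
    n, m = spec.n, spec.m
    group_b = rng_group.random(n) < spec.prop_b

    race_ind = np.zeros(m)
    race_ind[structure.race_edges] = 1.0
    conn: dict[str, ConnectivitySet] = {}
    z_first: np.ndarray | None = None
    for task in spec.tasks:
        z = (
            spec.baseline_z
            + spec.edge_effect * np.outer(group_b, race_ind)
            + rng_edges.normal(0.0, spec.sigma_z, size=(n, m))
        )
        if z_first is None:
            z_first = z
        conn[task] = ConnectivitySet(
            task=task, values=np.tanh(z), edge_index=EdgeIndex(spec.p)
        )

    # SNPs: Binomial(2, q_group) with explicit missingness
    q_subject = np.where(
        group_b[:, None], structure.q_group_b[None, :], structure.q_group_a[None, :]
    )
    dosage = rng_snp.binomial(2, q_subject).astype(float)
    missing = rng_miss.random((n, spec.n_snps)) < spec.snp_missing_rate
    dosage_obs = dosage.copy()
    dosage_obs[missing] = np.nan
    snp_ids = [f"rs{j + 1:06d}" for j in range(spec.n_snps)]
    snps = SNPDosageMatrix(snp_ids, dosage_obs) if spec.n_snps > 0 else None

    # score: group mean + direct edge path + direct SNP path + noise
    beta = spec.effective_score_effect()
    score = np.where(group_b, spec.score_mean_b, spec.score_mean_a).astype(float)
    if beta != 0.0 and len(structure.direct_edges) and z_first is not None:
        score = score + beta * (
            z_first[:, structure.direct_edges] - spec.baseline_z
        ).sum(axis=1)
    if spec.snp_score_ids:
        ids = list(spec.snp_score_ids)
        # center each dosage at its group's expectation so the direct SNP
        # path is orthogonal to group and does not inflate the score gap
        centered = dosage[:, ids] - 2.0 * q_subject[:, ids]
        score = score + spec.snp_score_effect * centered.sum(axis=1)
    score = score + rng_score.normal(0.0, spec.score_sd, size=n)

    age = rng_age.integers(
        spec.age_range_months[0], spec.age_range_months[1] + 1, size=n
    ).astype(float)
    sex = (rng_sex.random(n) < 0.5).astype(float)
    mother_edu = np.round(
        np.clip(rng_edu.normal(np.where(group_b, 12.5, 15.0), 2.5), 6, 22)
    )
    father_edu = np.round(
        np.clip(rng_edu.normal(np.where(group_b, 12.5, 15.0), 2.5), 6, 22)
    )
    father_edu[rng_edu.random(n) < 0.3] = np.nan  # planted missingness

    df = pd.DataFrame(
        {
            "race": np.where(group_b, "B", "A"),
            "race_code": group_b.astype(float),
            "sex": sex,
            "age_months": age,
            "wrat": score,
            "mother_education": mother_edu,
            "father_education": father_edu,
        },
        index=pd.Index([f"sub{i:05d}" for i in range(n)], name="subject_id"),
    )
    pheno = PhenotypeTable(
        df,
        kinds={
            "race": "categorical",
            "race_code": "binary",
            "sex": "binary",
            "age_months": "continuous",
            "wrat": "continuous",
            "mother_education": "continuous",
            "father_education": "continuous",
        },
        units={
            "age_months": "months",
            "mother_education": "years",
            "father_education": "years",
        },
    )
    return Cohort(
        pheno, conn, snps, name=f"synthetic-{spec.scenario}-seed{spec.seed}"
    )


def generate_timeseries(
    cov: np.ndarray, T: int, seed: int, subject_id: str = "", task: str = ""
) -> TimeseriesMatrix:
    """Region x time draws from a zero-mean multivariate normal.

    Ground truth for connectivity estimators: as T grows the sample FC
    converges to the correlation form of ``cov``.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise SpecError("covariance must be square")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SpecError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    values = L @ rng.standard_normal((cov.shape[0], T))
    return TimeseriesMatrix(values, subject_id=subject_id, task=task)


def plant_snp_overlap(spec: SyntheticSpec, k: int, shared: int) -> SyntheticSpec:
    """Plant a top-k SNP overlap between group divergence and score effect.

    SNPs ``0..k-1`` get strong planted group divergence; SNPs
    ``k-shared..2k-shared-1`` get a direct score effect; exactly
    ``shared`` SNPs carry both.  With strong effects and enough subjects,
    ranking SNPs by |correlation| with group and with score recovers an
    overlap of ``shared`` up to sampling error.
    """
    if not 0 <= shared <= k:
        raise SpecError(f"need 0 <= shared <= k, got shared={shared}, k={k}")
    if 2 * k - shared > spec.n_snps:
        raise SpecError(
            f"need {2 * k - shared} distinct SNPs but spec has {spec.n_snps}"
        )
    return replace(
        spec,
        snp_race_ids=tuple(range(k)),
        snp_score_ids=tuple(range(k - shared, 2 * k - shared)),
    )
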