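"""Synthetic survival cohorts and expression matrices with known ground truth.

The generator reproduces the statistical structure of a chronic
drug-intervention lifespan study: four animal groups (control/treated ×
male/female) with Gompertz-family death times, and Illumina-style intensity
matrices in which treated females respond broadly, a latent Bernoulli
"responder" subgroup of treated males echoes part of the female response, and
a block of sex-specific probes separates the sexes.  Every planted effect is
returned as a ``SyntheticTruth`` so downstream stages can be scored against
the truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rapalife.mortality import CohortSurvival, GompertzFamilyModel, survival


@dataclass
class CohortDesign:
    """Study design for a simulated survival cohort.

    ``groups`` maps group labels to (sex, diet, hazard model); ``n_per_group``
    is either a single count or a per-label mapping.
    """

    groups: dict[str, tuple[str, str, GompertzFamilyModel]]
    n_per_group: int | dict[str, int]
    censor_fraction: float = 0.0
    seed: int = 0

    def n_for(self, label: str) -> int:
        n = self.n_per_group[label] if isinstance(self.n_per_group, dict) else self.n_per_group
        if n < 2:
            raise ValueError(f"n_per_group must be >= 2, got {n} for {label!r}")
        return int(n)

    def __post_init__(self):
        if not (0.0 <= self.censor_fraction < 1.0):
            raise ValueError(f"censor_fraction must be in [0, 1), got {self.censor_fraction}")


@dataclass
class ExpressionDesign:
    """Design of a simulated probes × samples intensity matrix (linear scale).

    Defaults keep the study's proportions at a reduced probe count: sex-specific
    probes ~1.5% of the array and treatment-responsive probes ~18.5%, so the
    treatment signature dominates the sex signature in the ordination the way
    a broad hepatic drug response dominates a few hundred dimorphic genes.
    """

    n_probes: int = 2000
    samples_per_group: dict[str, int] = field(default_factory=lambda: {
        "control_male": 12, "rapa_male": 13, "control_female": 12, "rapa_female": 12})
    n_sex_genes: int = 30
    sex_shift: float = 1.5
    n_de_genes: int = 370
    de_shift: float = 1.0
    responder_fraction: float = 6 / 13
    responder_share: float = 0.8
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 1 or any(n < 1 for n in self.samples_per_group.values()):
            raise ValueError("all counts must be >= 1")
        for name in ("responder_fraction", "responder_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_sex_genes + self.n_de_genes > self.n_probes:
            raise ValueError(
                f"effect-gene counts ({self.n_sex_genes}+{self.n_de_genes}) exceed n_probes "
                f"({self.n_probes})")


@dataclass
class SyntheticTruth:
    """Planted effects: one entry per generated unit, covering every unit once."""

    group_hazard: dict | None = None            # per-animal group -> hazard model
    responder: pd.Series | None = None          # per treated-male sample: bool
    de_direction: pd.DataFrame | None = None    # probe × contrast: -1/0/+1
    sex_gene: pd.Series | None = None           # per probe: bool
    planted_sets: dict | None = None            # set name -> bool


def default_lifespan_design(seed: int = 0, censor_fraction: float = 0.0) -> CohortDesign:
    """The study's group sizes with realistic C57BL/6 hazards.

    40 control males and 45 animals in each other group; treatment reduces
    the rate-of-aging parameter b (~11% male / ~15% female median extension).
    """
    g = GompertzFamilyModel
    return CohortDesign(
        groups={
            "control_male": ("male", "control", g("gompertz", a=0.003, b=0.15)),
            "rapa_male": ("male", "rapa", g("gompertz", a=0.003, b=0.13)),
            "control_female": ("female", "control", g("gompertz", a=0.0025, b=0.155)),
            "rapa_female": ("female", "rapa", g("gompertz", a=0.0025, b=0.128)),
        },
        n_per_group={"control_male": 40, "rapa_male": 45,
                     "control_female": 45, "rapa_female": 45},
        censor_fraction=censor_fraction,
        seed=seed,
    )


def sample_death_times(model: GompertzFamilyModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of death times from a Gompertz-family hazard.

    The pure Gompertz inverse is closed-form,
    x = (1/b)·ln(1 − (b/a)·ln U); the Makeham/logistic variants are solved by
    bisection on S(x) − U with bracket expansion (exactness over speed).
    """
    u = rng.uniform(size=n)
    if model.family == "gompertz":
        return np.log1p(-(model.b / model.a) * np.log(u)) / model.b
    # S is strictly decreasing wherever the hazard is positive, so bisection
    # on S(x) - u is well posed once the bracket contains the root.
    times = np.empty(n)
    for i, ui in enumerate(u):
        hi = 1.0
        while survival(model, hi) > ui:
            hi *= 2.0
            if hi > 1e9:
                raise RuntimeError("bracket expansion failed; hazard too small")
        lo = 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if survival(model, mid) > ui:
                lo = mid
            else:
                hi = mid
        times[i] = 0.5 * (lo + hi)
    return times


def simulate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-animal ages at death for every group in the design.

    Returns a survival table (id, group, sex, diet, age_at_death_months,
    event) and the truth.  When ``censor_fraction`` > 0, that fraction of
    animals per group is right-censored at a Uniform(0, t_death) time.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    hazards = {}
    for label, (sex, diet, model) in design.groups.items():
        n = design.n_for(label)
        hazards[label] = model
        times = sample_death_times(model, n, rng)
        events = np.ones(n, dtype=bool)
        n_cens = int(np.floor(design.censor_fraction * n))
        if n_cens:
            idx = rng.choice(n, size=n_cens, replace=False)
            events[idx] = False
            times[idx] *= rng.uniform(size=n_cens)
            times[idx] = np.maximum(times[idx], 1e-6)
        for j in range(n):
            rows.append((f"{label}_{j:03d}", label, sex, diet, times[j], events[j]))
    df = pd.DataFrame(rows, columns=["id", "group", "sex", "diet",
                                     "age_at_death_months", "event"])
    return df, SyntheticTruth(group_hazard=hazards)


def cohort_from_frame(df: pd.DataFrame, group: str | None = None) -> CohortSurvival:
    """Extract a (optionally single-group) CohortSurvival from a survival table."""
    sub = df if group is None else df[df["group"] == group]
    return CohortSurvival.from_dataframe(sub)


def simulate_expression(design: ExpressionDesign) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a linear-scale intensity matrix with planted effects.

    Returns (intensities probes × samples, sample metadata, truth).  The
    log2-scale signal is baseline + sex shift + treatment shift + Gaussian
    noise; intensities are exp2 of that, hence strictly positive.  Treated
    females carry the full treatment effect; each treated male is a responder
    with probability ``responder_fraction`` and responders echo a random
    ``responder_share`` of the female-response genes.  Non-responder males
    have the control-male expectation.
    """
    rng = np.random.default_rng(design.seed)
    probes = np.array([f"probe_{i:05d}" for i in range(design.n_probes)])

    sample_ids, meta_rows = [], []
    for grp, n in design.samples_per_group.items():
        sex = "female" if "female" in grp else "male"
        diet = "rapa" if grp.startswith("rapa") else "control"
        for j in range(n):
            sid = f"{grp}_{j:02d}"
            sample_ids.append(sid)
            meta_rows.append((sid, grp, sex, diet))
    meta = pd.DataFrame(meta_rows, columns=["sample", "group", "sex", "diet"]).set_index("sample")

    # responder labels for treated males (independent Bernoulli per animal)
    treated_male = meta.index[(meta["sex"] == "male") & (meta["diet"] == "rapa")]
    responder = pd.Series(
        rng.uniform(size=len(treated_male)) < design.responder_fraction,
        index=treated_male)

    perm = rng.permutation(design.n_probes)
    sex_idx = perm[:design.n_sex_genes]
    de_idx = perm[design.n_sex_genes:design.n_sex_genes + design.n_de_genes]

    baseline = rng.uniform(*design.baseline_range, size=design.n_probes)
    sex_sign = rng.choice([-1.0, 1.0], size=design.n_sex_genes)     # +1 => higher in males
    de_sign = rng.choice([-1.0, 1.0], size=design.n_de_genes)

    # which female-response genes are echoed in responder males
    echo_mask = rng.uniform(size=design.n_de_genes) < design.responder_share

    log2_means = np.tile(baseline[:, None], (1, len(sample_ids)))
    de_dir = pd.DataFrame(0, index=probes,
                          columns=["female_treated", "male_responder"], dtype=int)
    de_dir.iloc[de_idx, 0] = de_sign.astype(int)
    de_dir.iloc[de_idx[echo_mask], 1] = de_sign[echo_mask].astype(int)

    for k, sid in enumerate(sample_ids):
        row = meta.loc[sid]
        if row["sex"] == "male":
            log2_means[sex_idx, k] += design.sex_shift * sex_sign
        if row["diet"] == "rapa":
            if row["sex"] == "female":
                log2_means[de_idx, k] += design.de_shift * de_sign
            elif responder.get(sid, False):
                log2_means[de_idx[echo_mask], k] += design.de_shift * de_sign[echo_mask]

    log2_values = log2_means + rng.normal(0.0, design.noise_sd, size=log2_means.shape)
    intensities = pd.DataFrame(np.exp2(log2_values), index=probes, columns=sample_ids)

    truth = SyntheticTruth(
        responder=responder,
        de_direction=de_dir,
        sex_gene=pd.Series(np.isin(np.arange(design.n_probes), sex_idx), index=probes),
    )
    return intensities, meta, truth


def simulate_gene_sets(universe: list[str], de_labels: pd.Series, *,
                       n_sets: int = 20, set_size: int = 50, n_planted: int = 2,
                       odds_ratio: float = 5.0, seed: int = 0):
    """Build a gene-set catalog with planted DE-enriched sets over a universe.

    Planted sets sample members with selection weight ``odds_ratio`` on DE
    genes (weighted sampling without replacement); decoy sets are uniform
    draws.  With ``odds_ratio`` = 1 nothing is planted.  Returns a
    GeneSetCollection and a SyntheticTruth with per-set planted flags.
    """
    from rapalife.enrichment import GeneSetCollection

    universe = list(universe)
    if set_size > len(universe):
        raise ValueError(f"set size {set_size} exceeds universe size {len(universe)}")
    if odds_ratio < 1.0:
        raise ValueError(f"odds_ratio must be >= 1, got {odds_ratio}")
    rng = np.random.default_rng(seed)
    de = de_labels.reindex(universe).fillna(False).to_numpy(bool)
    if odds_ratio == 1.0:
        n_planted = 0

    sets, flags = {}, {}
    for i in range(n_sets):
        name = f"set_{i:03d}"
        planted = i < n_planted
        if planted:
            w = np.where(de, odds_ratio, 1.0)
            p = w / w.sum()
            members = rng.choice(universe, size=set_size, replace=False, p=p)
        else:
            members = rng.choice(universe, size=set_size, replace=False)
        sets[name] = sorted(members.tolist())
        flags[name] = planted
    coll = GeneSetCollection(sets=sets, universe=universe)
    return coll, SyntheticTruth(planted_sets=flags)


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "sex", "diet", "age_at_death_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    df["event"] = df["event"].astype(bool)
    return df
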