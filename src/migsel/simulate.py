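"""Synthetic cohort generator for selective-association analyses.

Emulates the structure of a large all-female population cohort with
genotyped candidate SNPs: independent loci in Hardy-Weinberg equilibrium,
an active-migraineur fraction near 14%, ten binary migraine characteristics
with configurable prevalences among cases (defaults follow the all-migraineur
symptom profile of the study population), and genotype effects injected
under any of the six association models so that every downstream stage can
be tested against known truth.

Symptom profiles exist only for active migraineurs, mirroring questionnaire
skip logic; "prior" migraineurs are generated solely to exercise the
exclusion filter.  One global seed determines everything; per-stage child
seeds are spawned from ``numpy.random.SeedSequence(seed)`` in the fixed
order (genotypes, status, symptoms, covariates, prior), so stages are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .trinomial import MODELS, ValidationError

__all__ = [
    "SYMPTOMS",
    "DEFAULT_PREVALENCES",
    "SimConfig",
    "SnpEffect",
    "LcaTruth",
    "GenotypeMatrix",
    "Cohort",
    "gen_genotypes",
    "gen_phenotypes_trichotomous",
    "gen_cohort",
    "gen_latent_class_cases",
    "ld_r2",
]

#: the ten binary migraine characteristics, in report order
SYMPTOMS = (
    "aura", "pulsating", "unilateral", "phonophobia", "photophobia",
    "duration_4_72h", "nausea_vomiting", "aggravation_physical",
    "inhibits_daily", "freq_ge6",
)

#: default per-symptom prevalence among active migraineurs
#: (all-migraineur column of the cohort's symptom table)
DEFAULT_PREVALENCES = {
    "aura": 0.392, "pulsating": 0.530, "unilateral": 0.596,
    "phonophobia": 0.410, "photophobia": 0.668, "duration_4_72h": 0.781,
    "nausea_vomiting": 0.652, "aggravation_physical": 0.339,
    "inhibits_daily": 0.499, "freq_ge6": 0.350,
}

_TRINOMIAL_MODELS = ("basic", "subset", "inverse_subset", "general")


@dataclass
class SnpEffect:
    """Association injected at one SNP.

    ``model`` is one of the six; selective/trinomial models act on the
    case-vs-control logits for ``target`` (basic ignores the target), the
    modifier acts on the symptom-given-case logit.  Log-odds parameters:
    ``beta_minus``/``beta_plus`` per dose for the trinomial contrasts
    (``beta`` shorthand sets both for basic), ``gamma`` for the modifier.
    """

    snp: str
    model: str = "null"
    target: str | None = None
    beta_minus: float = 0.0
    beta_plus: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValidationError(f"unknown effect model {self.model!r}")
        if self.model == "subset" and self.beta_minus != 0.0:
            raise ValidationError("subset model forces beta_minus = 0")
        if self.model == "inverse_subset" and self.beta_plus != 0.0:
            raise ValidationError("inverse_subset model forces beta_plus = 0")
        if self.model == "basic" and self.beta_minus != self.beta_plus:
            raise ValidationError("basic model requires beta_minus == beta_plus")
        if self.model in ("subset", "inverse_subset", "general", "modifier") \
                and self.target is None:
            raise ValidationError(f"{self.model} effect needs a target symptom")
        if self.target is not None and self.target not in SYMPTOMS:
            raise ValidationError(f"unknown target symptom {self.target!r}")


@dataclass
class LcaTruth:
    """Ground-truth latent class mixture: weights pi (K,) and item-response
    probabilities rho (K, 10) over the symptom items."""

    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.rho = np.asarray(self.rho, float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi < 0).any():
            raise ValidationError("class weights must be a probability vector")
        if self.rho.ndim != 2 or self.rho.shape[0] != self.pi.size \
                or self.rho.shape[1] != len(SYMPTOMS):
            raise ValidationError(
                f"rho must be (K, {len(SYMPTOMS)}) matching pi")
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValidationError("item-response probabilities must lie in [0,1]")


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort; the seed fixes everything."""

    n_participants: int = 21111
    maf_per_snp: list[float] = field(default_factory=lambda: [0.3])
    case_fraction: float = 0.14
    symptom_model: str = "independent"  # or "latent_class"
    symptom_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    lca_truth: LcaTruth | None = None
    snp_effects: list[SnpEffect] = field(default_factory=list)
    prior_fraction: float = 0.09
    age_mean: float = 54.6
    age_sd: float = 7.2
    age_min: float = 45.0
    n_pcs: int = 10
    confounder_loading: float = 0.0  # loading of pc1 on the case logit
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for q in self.maf_per_snp:
            if not 0.0 < q <= 0.5:
                raise ValidationError(f"minor allele frequency {q} outside (0, 0.5]")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must lie in (0, 1)")
        if self.symptom_model not in ("independent", "latent_class"):
            raise ValidationError("symptom_model must be independent or latent_class")
        if self.symptom_model == "latent_class" and self.lca_truth is None:
            raise ValidationError("latent_class symptom model requires lca_truth")
        for s, p in self.symptom_prevalences.items():
            if s not in SYMPTOMS:
                raise ValidationError(f"unknown symptom {s!r}")
            if not 0.0 <= p <= 1.0:
                raise ValidationError("symptom prevalences must lie in [0,1]")
        if not 0.0 <= self.prior_fraction < 1.0 - self.case_fraction:
            raise ValidationError("prior_fraction must fit beside case_fraction")
        targets = {e.target for e in self.snp_effects
                   if e.model in ("subset", "inverse_subset", "general")}
        if len(targets) > 1:
            raise ValidationError(
                "selective trinomial effects must share one target symptom; "
                f"got {sorted(targets)}")


@dataclass
class GenotypeMatrix:
    """Hard-called dosages (participants x SNPs) with identifiers."""

    dosages: np.ndarray
    snp_ids: list[str]
    maf_declared: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        if ((self.dosages < 0) | (self.dosages > 2)).any():
            raise ValidationError("dosages must lie in [0, 2]")


@dataclass
class Cohort:
    """A generated cohort plus the ground truth that produced it."""

    genotypes: GenotypeMatrix
    migraine_status: np.ndarray  # 'none' | 'prior' | 'active'
    symptoms: np.ndarray  # (n, 10) float; NaN = not asked (non-active)
    age: np.ndarray
    pcs: np.ndarray
    truth: dict

    @property
    def n(self) -> int:
        return self.migraine_status.size

    def symptom_frame(self):
        import pandas as pd
        return pd.DataFrame(self.symptoms, columns=list(SYMPTOMS))


# ---------------------------------------------------------------------------

def _child_rngs(seed: int, n: int = 5):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_genotypes(n: int, mafs, seed: int = 0,
                  rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw hard-call genotypes under Hardy-Weinberg equilibrium.

    For allele frequency q the dose distribution is
    P(0,1,2) = ((1-q)^2, 2q(1-q), q^2), independent across SNPs.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    mafs = np.asarray(mafs, float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValidationError("each maf must lie in (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    # dose = sum of two Bernoulli(q) allele draws
    dos = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    ids = [f"snp{i + 1}" for i in range(mafs.size)]
    return GenotypeMatrix(dosages=dos, snp_ids=ids, maf_declared=mafs)


def _trinomial_probs(g, alpha_minus, alpha_plus, beta_minus, beta_plus):
    eta1 = alpha_minus + beta_minus * g
    eta2 = alpha_plus + beta_plus * g
    denom = np.logaddexp(0.0, np.logaddexp(eta1, eta2))
    p1 = np.exp(eta1 - denom)
    p2 = np.exp(eta2 - denom)
    return np.stack([1.0 - p1 - p2, p1, p2], axis=-1)


def gen_phenotypes_trichotomous(g, model: str, params: dict, seed: int = 0,
                                rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a three-group outcome vector directly from one association model.

    ``params`` carries ``alpha_minus``, ``alpha_plus``, ``beta_minus``,
    ``beta_plus`` (trinomial models; constraints enforced) or ``a``, ``c``,
    ``gamma`` for the factorized modifier model.
    """
    g = np.asarray(g, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if model == "modifier":
        p_case = 1.0 / (1.0 + np.exp(-params["a"]))
        case = rng.random(g.size) < p_case
        p_sym = 1.0 / (1.0 + np.exp(-(params["c"] + params["gamma"] * g)))
        sym = rng.random(g.size) < p_sym
        return np.where(case, np.where(sym, 2, 1), 0).astype(np.int8)
    bm = params.get("beta_minus", 0.0)
    bp = params.get("beta_plus", 0.0)
    if model == "null" and (bm != 0 or bp != 0):
        raise ValidationError("null model forces both slopes to 0")
    if model == "basic" and bm != bp:
        raise ValidationError("basic model requires beta_minus == beta_plus")
    if model == "subset" and bm != 0:
        raise ValidationError("subset model forces beta_minus = 0")
    if model == "inverse_subset" and bp != 0:
        raise ValidationError("inverse_subset model forces beta_plus = 0")
    if model == "null":
        bm = bp = 0.0
    probs = _trinomial_probs(g, params["alpha_minus"], params["alpha_plus"], bm, bp)
    u = rng.random(g.size)
    cum = probs.cumsum(axis=-1)
    return (u[:, None] >= cum).sum(axis=-1).astype(np.int8)


def _draw_symptoms(rng, n_cases, config: SimConfig):
    """Item matrix (n_cases, 10) and, in latent mode, the true class labels."""
    prev = np.array([config.symptom_prevalences.get(s, DEFAULT_PREVALENCES[s])
                     for s in SYMPTOMS])
    if config.symptom_model == "independent":
        return (rng.random((n_cases, len(SYMPTOMS))) < prev).astype(float), None
    truth = config.lca_truth
    z = rng.choice(truth.pi.size, size=n_cases, p=truth.pi)
    items = (rng.random((n_cases, len(SYMPTOMS))) < truth.rho[z]).astype(float)
    return items, z


def gen_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort under the configured ground truth.

    Trinomial-type SNP effects act on the two case-vs-control logits of the
    target symptom's three-group outcome; ``case_fraction`` and the target
    symptom's prevalence anchor the intercepts at zero dose.  Modifier
    effects tilt the symptom-given-case logit with a genotype-free case
    margin.  With all-null effects, symptoms are independent of genotype.
    """
    rng_geno, rng_status, rng_sym, rng_cov, rng_prior = _child_rngs(config.seed)
    n = config.n_participants
    geno = gen_genotypes(n, config.maf_per_snp, rng=rng_geno)
    snp_index = {s: i for i, s in enumerate(geno.snp_ids)}

    tri_effects = [e for e in config.snp_effects if e.model in _TRINOMIAL_MODELS]
    mod_effects = [e for e in config.snp_effects if e.model == "modifier"]
    for e in config.snp_effects:
        if e.snp not in snp_index:
            raise ValidationError(f"effect references unknown SNP {e.snp!r}")

    # covariates first (the confounder, when enabled, enters the case logit)
    from scipy.stats import truncnorm
    a = (config.age_min - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng_cov)
    pcs = rng_cov.standard_normal((n, config.n_pcs))
    confound = config.confounder_loading * pcs[:, 0] if config.n_pcs else 0.0

    f = config.case_fraction
    target = next((e.target for e in tri_effects if e.target is not None), None)
    if target is None and tri_effects:
        target = SYMPTOMS[0]  # basic-only effects: symptom split is arbitrary

    if tri_effects:
        p_t = config.symptom_prevalences.get(target, DEFAULT_PREVALENCES[target])
        am = np.log(f * (1 - p_t) / (1 - f))
        ap = np.log(f * p_t / (1 - f))
        eta1 = np.full(n, am) + confound
        eta2 = np.full(n, ap) + confound
        for e in tri_effects:
            gvec = geno.dosages[:, snp_index[e.snp]]
            eta1 += e.beta_minus * gvec
            eta2 += e.beta_plus * gvec
        # pass g=0 so the fully-formed etas are used as-is
        probs = _trinomial_probs(0.0, eta1, eta2, 0.0, 0.0)
        u = rng_status.random(n)
        tri = (u[:, None] >= probs.cumsum(-1)).sum(-1).astype(np.int8)
        active = tri > 0
    else:
        eta = np.log(f / (1 - f)) + confound
        active = rng_status.random(n) < 1.0 / (1.0 + np.exp(-eta))
        tri = None

    status = np.where(active, "active", "none").astype(object)
    # prior migraineurs: a marginal cohort fraction, carved out of non-actives
    if config.prior_fraction > 0:
        p_prior = config.prior_fraction / max(1e-12, 1.0 - f)
        mark = (~active) & (rng_prior.random(n) < p_prior)
        status[mark] = "prior"

    symptoms = np.full((n, len(SYMPTOMS)), np.nan)
    idx_case = np.flatnonzero(active)
    items, z = _draw_symptoms(rng_sym, idx_case.size, config)
    if tri is not None and target is not None:
        items[:, SYMPTOMS.index(target)] = (tri[idx_case] == 2).astype(float)
    for e in mod_effects:
        j = SYMPTOMS.index(e.target)
        p0 = config.symptom_prevalences.get(e.target, DEFAULT_PREVALENCES[e.target])
        gvec = geno.dosages[idx_case, snp_index[e.snp]]
        eta = np.log(p0 / (1 - p0)) + e.gamma * gvec
        items[:, j] = (rng_sym.random(idx_case.size) < 1 / (1 + np.exp(-eta))).astype(float)
    symptoms[idx_case] = items

    truth = {
        "config": _config_record(config),
        "per_snp": {s: "null" for s in geno.snp_ids},
        "true_class": None if z is None else z.tolist(),
    }
    for e in config.snp_effects:
        truth["per_snp"][e.snp] = e.model
    return Cohort(genotypes=geno, migraine_status=np.asarray(status),
                  symptoms=symptoms, age=age, pcs=pcs, truth=truth)


def _config_record(config: SimConfig) -> dict:
    rec = asdict(config)
    if config.lca_truth is not None:
        rec["lca_truth"] = {"pi": config.lca_truth.pi.tolist(),
                            "rho": config.lca_truth.rho.tolist()}
    return rec


def gen_latent_class_cases(n: int, case_fraction: float, maf: float,
                           pi, rho, class_gamma=None, seed: int = 0):
    """Latent-class cases competing with controls in one multinomial logit.

    Each participant falls in {control} union the K classes with
    log-odds-vs-control  eta_k = log(f * pi_k / (1 - f)) + gamma_k * dose,
    so a nonzero ``class_gamma[k]`` raises the odds of class k relative to
    controls only — the class-membership analog of the subset model.  Case
    items are drawn from the class's response profile rho.  Returns
    (g, items, true_class, case_mask); ``items`` covers cases only, in
    case order.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, float)
    rho = np.asarray(rho, float)
    K, J = rho.shape
    g = rng.binomial(2, maf, size=n).astype(float)
    f = case_fraction
    gamma = np.zeros(K) if class_gamma is None else np.asarray(class_gamma, float)
    eta = np.log(f * pi / (1 - f))[None, :] + np.outer(g, gamma)
    denom = 1.0 + np.exp(eta).sum(1)
    p = np.column_stack([np.ones(n), np.exp(eta)]) / denom[:, None]
    cat = (rng.random(n)[:, None] >= p.cumsum(1)).sum(1)
    case_mask = cat > 0
    z = cat[case_mask] - 1
    items = (rng.random((case_mask.sum(), J)) < rho[z]).astype(float)
    return g, items, z, case_mask


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape or g1.size < 3:
        raise ValidationError("dosage vectors must share length >= 3")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValidationError("LD undefined for a monomorphic dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)
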