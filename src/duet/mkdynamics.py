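"""Generative inheritance model of CI, late-acting MK and a dominant
nuclear suppressor.

The model tracks three things per individual: sex, the nuclear suppressor
genotype (number of dominant S alleles), and the cytotype — the set of
symbiont strains carried, a subset of {CI, MK}, acquired strictly
maternally.  Four phenotypic rules connect them:

* **CI** — a cross of a CI-carrying male to a female lacking the CI strain
  hatches at ``h_ci`` instead of the baseline ``h_0``; a CI-carrying
  mother (whatever else she carries) rescues fully.
* **late MK** — a male offspring that inherits the MK strain and carries
  no functional suppressor dies at the larval stage with probability
  ``mu`` (so MK halves egg-to-adult viability of a brood rather than egg
  hatch); ``leak`` is the probability MK fails to act in such a male.
* **maternal transmission** — each strain the mother carries is passed to
  each offspring independently with probability ``tau_ci`` / ``tau_mk``.
* **suppression** — one S allele suffices (dominant) and protects a male
  with probability ``penetrance``.

On top of the per-cross calculator sit a stochastic backcross-panel
simulator (the segregation design), a mixed-vial population simulator (the
suppressor-spread design), and the field-screening statistics (likelihood
ratio G-test, 50:50 sex-ratio chi-square, qPCR relative density).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IndividualGenotype",
    "ModelParams",
    "CrossOutcome",
    "expected_cross_outcome",
    "sample_brood",
    "classify_line_phenotype",
    "simulate_backcross_panel",
    "simulate_mixed_population",
    "g_test",
    "sex_ratio_chisq",
    "relative_density",
    "percent",
    "incidence_table",
]

FEMALE = "female"
MALE = "male"


@dataclass(frozen=True)
class IndividualGenotype:
    """(sex, suppressor genotype, cytotype).  ``s_alleles`` counts dominant
    S copies (0 = ss, 1 = Ss, 2 = SS); ``cytotype`` is the frozenset of
    strains carried, a subset of {"CI", "MK"}."""

    sex: str
    s_alleles: int = 0
    cytotype: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError("sex must be 'female' or 'male'")
        if self.s_alleles not in (0, 1, 2):
            raise ValueError("s_alleles must be 0, 1 or 2")
        object.__setattr__(self, "cytotype", frozenset(self.cytotype))
        if not self.cytotype <= {"CI", "MK"}:
            raise ValueError("cytotype must be a subset of {'CI', 'MK'}")

    @property
    def nuclear(self) -> str:
        return ("ss", "Ss", "SS")[self.s_alleles]


def female(s_alleles: int = 0, cytotype=()) -> IndividualGenotype:
    return IndividualGenotype(FEMALE, s_alleles, frozenset(cytotype))


def male(s_alleles: int = 0, cytotype=()) -> IndividualGenotype:
    return IndividualGenotype(MALE, s_alleles, frozenset(cytotype))


@dataclass(frozen=True)
class ModelParams:
    """Inheritance-model parameters (all probabilities).

    Defaults reflect the measured system: near-perfect CI-strain
    transmission, 71/73 MK-strain transmission, 6.17% incompatible-cross
    hatch against a 76% baseline, baseline egg-to-adult viability 0.7,
    fully penetrant late MK (mu = 1, leak = 0) and fully dominant
    suppression.  ``male_ci_loss`` lets a CI father fail to induce (CI
    stays strong despite low male titer, so it defaults to 0).  Egg
    numbers are per female per laying day; broods accumulate over
    ``laying_days`` days.
    """

    tau_ci: float = 1.0
    tau_mk: float = 71.0 / 73.0
    h_ci: float = 0.0617
    h_0: float = 0.76
    v_0: float = 0.7
    mu: float = 1.0
    leak: float = 0.0
    penetrance: float = 1.0
    male_ci_loss: float = 0.0
    sex_ratio_0: float = 0.5
    eggs_per_day: float = 18.0
    laying_days: int = 4
    min_eggs_scored: int = 7

    def __post_init__(self) -> None:
        for name in ("tau_ci", "tau_mk", "h_ci", "h_0", "v_0", "mu", "leak",
                     "penetrance", "male_ci_loss", "sex_ratio_0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mu + self.leak > 1.0:
            raise ValueError("mu + leak must not exceed 1")

    @property
    def eggs_per_brood(self) -> float:
        return self.eggs_per_day * self.laying_days


@dataclass
class CrossOutcome:
    """Deterministic expectations for one cross.

    ``offspring_dist`` is the genotype distribution *among surviving
    adults* (probabilities sum to 1); ``categories`` keeps the underlying
    (genotype, egg-probability, survival-probability) triples used for
    sampling.
    """

    expected_hatch: float
    expected_egg_to_adult: float
    expected_prop_female: float
    offspring_dist: list[tuple[IndividualGenotype, float]]
    categories: list[tuple[IndividualGenotype, float, float]] = field(repr=False,
                                                                      default_factory=list)


def _mendel(mother_s: int, father_s: int) -> dict[int, float]:
    """Offspring S-allele-count distribution."""
    pm, pf = mother_s / 2.0, father_s / 2.0
    return {
        0: (1 - pm) * (1 - pf),
        1: pm * (1 - pf) + (1 - pm) * pf,
        2: pm * pf,
    }


def expected_cross_outcome(
    mother: IndividualGenotype, father: IndividualGenotype, p: ModelParams
) -> CrossOutcome:
    """Enumerate offspring categories and their hatch/survival expectations.

    Hatch is ``h_ci`` when the father carries CI and the mother does not
    (an MK-carrying mother without CI gets no rescue; a CI-carrying mother
    is fully compatible).  Cytotype is drawn from the mother only; a male
    inheriting MK without effective suppression dies before adulthood with
    probability ``(1 - leak) * mu``.  ``expected_egg_to_adult`` is per egg
    laid: ``v_0`` scaled by relative hatch and MK mortality.
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("cross requires a female mother and a male father")

    if "CI" in father.cytotype and "CI" not in mother.cytotype:
        hatch = p.h_ci * (1 - p.male_ci_loss) + p.h_0 * p.male_ci_loss
    else:
        hatch = p.h_0

    p_ci = p.tau_ci if "CI" in mother.cytotype else 0.0
    p_mk = p.tau_mk if "MK" in mother.cytotype else 0.0
    cyto_dist = {
        frozenset(): (1 - p_ci) * (1 - p_mk),
        frozenset({"CI"}): p_ci * (1 - p_mk),
        frozenset({"MK"}): (1 - p_ci) * p_mk,
        frozenset({"CI", "MK"}): p_ci * p_mk,
    }
    s_dist = _mendel(mother.s_alleles, father.s_alleles)
    hatch_factor = hatch / p.h_0 if p.h_0 > 0 else 0.0

    categories: list[tuple[IndividualGenotype, float, float]] = []
    for sex, p_sex in ((FEMALE, p.sex_ratio_0), (MALE, 1 - p.sex_ratio_0)):
        for s, p_s in s_dist.items():
            for cyto, p_cyto in cyto_dist.items():
                prob = p_sex * p_s * p_cyto
                if prob == 0.0:
                    continue
                survive = p.v_0 * hatch_factor
                if sex == MALE and "MK" in cyto:
                    unsuppressed = 1.0 if s == 0 else (1.0 - p.penetrance)
                    survive *= 1.0 - unsuppressed * (1.0 - p.leak) * p.mu
                categories.append(
                    (IndividualGenotype(sex, s, cyto), prob, survive)
                )

    egg_to_adult = sum(pr * sv for _, pr, sv in categories)
    if egg_to_adult > 0:
        dist = [(g, pr * sv / egg_to_adult) for g, pr, sv in categories if sv > 0]
        prop_female = sum(w for g, w in dist if g.sex == FEMALE)
    else:
        dist, prop_female = [], float("nan")
    return CrossOutcome(
        expected_hatch=hatch,
        expected_egg_to_adult=egg_to_adult,
        expected_prop_female=prop_female,
        offspring_dist=dist,
        categories=categories,
    )


def sample_brood(
    mother: IndividualGenotype,
    father: IndividualGenotype,
    n_eggs: int,
    p: ModelParams,
    rng: np.random.Generator,
) -> list[IndividualGenotype]:
    """Draw the surviving adult offspring of one brood of ``n_eggs`` eggs."""
    out = expected_cross_outcome(mother, father, p)
    if n_eggs == 0 or not out.categories:
        return []
    probs = np.array([pr * sv for _, pr, sv in out.categories])
    death = 1.0 - probs.sum()
    counts = rng.multinomial(n_eggs, np.append(probs, max(death, 0.0)))
    adults: list[IndividualGenotype] = []
    for (geno, _, _), k in zip(out.categories, counts):
        adults.extend([geno] * int(k))
    return adults


def classify_line_phenotype(
    n_female: int,
    n_male: int,
    min_total: int = 15,
    female_only_max_males: int = 0,
    mixed_max_prop_female: float = 0.70,
) -> str:
    """Classify a line from its offspring sex counts.

    Fewer than ``min_total`` offspring -> ``excluded`` (ambiguous since MK
    may be leaky); no males -> ``MK``; a female proportion at or below
    ``mixed_max_prop_female`` -> ``MKS``; anything between — female-biased
    but not female-only — stays ``excluded``.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("offspring counts must be non-negative")
    total = n_female + n_male
    if total < min_total:
        return "excluded"
    if n_male <= female_only_max_males:
        return "MK"
    if n_female / total <= mixed_max_prop_female:
        return "MKS"
    return "excluded"


def _draw_brood_size(p: ModelParams, rng: np.random.Generator) -> int:
    """Eggs laid by one female over the laying window; broods below the
    scoring minimum are redrawn (unscoreable vials are replaced)."""
    while True:
        n = int(rng.poisson(p.eggs_per_brood))
        if n >= p.min_eggs_scored:
            return n


_RECURRENT_MALE = male(0, ())
_DONOR_FEMALE = female(2, ("CI", "MK"))


def simulate_backcross_panel(
    n_lines: int = 20,
    generations: int = 3,
    p: ModelParams | None = None,
    seed: int = 42,
    donor: IndividualGenotype = _DONOR_FEMALE,
    recurrent_male: IndividualGenotype = _RECURRENT_MALE,
) -> pd.DataFrame:
    """Simulate the segregation design: repeated single-female crosses to
    recurrent-line males, classifying each line's offspring sex ratio.

    Generation 0 tests the donor females themselves (the F1 brood);
    generation *k* tests females pooled from generation *k-1* broods (the
    backcross-*k* brood).  With S fixed in the donor the idealized
    expectation for the percent of female-only lines is 0 (F1), 0 (BC1),
    50 (BC2), 75 (BC3): the mothers of the BC-*k* brood are BC-(k-1)
    females, homozygous ss with probability 1 - (1/2)^(k-1).

    Returns one row per brood generation with observed and expected
    percentages (percent over all tested lines, as segregation tables
    report; excluded lines counted separately).
    """
    p = p or ModelParams()
    rng = np.random.default_rng(seed)
    mothers = [donor] * n_lines
    rows = []
    p_ss = 0.0  # P(mother is ss) for the idealized expectation
    for gen in range(generations + 1):
        label = "F1" if gen == 0 else f"BC{gen}"
        counts = {"MK": 0, "MKS": 0, "excluded": 0}
        daughters: list[IndividualGenotype] = []
        for mother in mothers:
            brood = sample_brood(
                mother, recurrent_male, _draw_brood_size(p, rng), p, rng
            )
            n_f = sum(1 for a in brood if a.sex == FEMALE)
            n_m = len(brood) - n_f
            counts[classify_line_phenotype(n_f, n_m)] += 1
            daughters.extend(a for a in brood if a.sex == FEMALE)
        n_tested = len(mothers)
        rows.append(
            {
                "generation": label,
                "n_tested": n_tested,
                "n_mk": counts["MK"],
                "n_mks": counts["MKS"],
                "n_excluded": counts["excluded"],
                "pct_mk": percent(counts["MK"], n_tested),
                "expected_pct_mk": 100.0 * p_ss * (p.tau_mk ** gen),
            }
        )
        if not daughters:
            break
        idx = rng.choice(len(daughters), size=min(n_lines, len(daughters)),
                         replace=False)
        mothers = [daughters[i] for i in idx]
        # mothers of the next brood are this brood's females: F1 females are
        # all Ss when S is fixed in the donor; thereafter ss w.p. (1 + p_ss)/2
        p_ss = 0.0 if gen == 0 else (1.0 + p_ss) / 2.0
    return pd.DataFrame(rows)


def simulate_mixed_population(
    init_mk_fraction: float,
    vial_size: int = 40,
    generations: int = 5,
    rescue_males: int = 5,
    p: ModelParams | None = None,
    n_replicates: int = 10,
    seed: int = 42,
) -> pd.DataFrame:
    """Track sex ratios in vials seeded with MK and MKS females.

    Founders are ``init_mk_fraction`` MK females (ss, carrying CI+MK,
    pre-mated to cured recurrent-line males) and the balance MKS females
    (SS, carrying CI+MK, pre-mated to MKS males).  Each generation every
    female mates once with a male drawn uniformly from the vial's males;
    when a vial has no males, ``rescue_males`` cured recurrent-line (ss,
    uninfected) males are supplied, mirroring how female-only lines are
    kept going.  The recorded sex ratio is the percent of females among
    all adults emerging that generation; the next generation breeds from a
    random sample of ``vial_size`` of them.  A vial with no emerging
    adults is truncated and flagged.
    """
    if not 0.0 <= init_mk_fraction <= 1.0:
        raise ValueError("init_mk_fraction must lie in [0, 1]")
    p = p or ModelParams()
    rng = np.random.default_rng(seed)
    rescue = male(0, ())
    mks_sire = male(2, ("CI", "MK"))

    rows = []
    for rep in range(n_replicates):
        n_mk = int(round(init_mk_fraction * vial_size))
        pairs = [(female(0, ("CI", "MK")), rescue) for _ in range(n_mk)]
        pairs += [(female(2, ("CI", "MK")), mks_sire)
                  for _ in range(vial_size - n_mk)]
        for gen in range(1, generations + 1):
            adults: list[IndividualGenotype] = []
            for mother, sire in pairs:
                adults.extend(
                    sample_brood(mother, sire, _draw_brood_size(p, rng), p, rng)
                )
            if not adults:
                rows.append({"replicate": rep, "generation": gen,
                             "n_adults": 0, "pct_female": np.nan,
                             "truncated": True})
                break
            n_f = sum(1 for a in adults if a.sex == FEMALE)
            rows.append(
                {"replicate": rep, "generation": gen, "n_adults": len(adults),
                 "pct_female": 100.0 * n_f / len(adults), "truncated": False}
            )
            idx = rng.choice(len(adults), size=min(vial_size, len(adults)),
                             replace=False)
            breeders = [adults[i] for i in idx]
            females = [a for a in breeders if a.sex == FEMALE]
            males = [a for a in breeders if a.sex == MALE]
            if not females:
                break
            if not males:
                males = [rescue] * rescue_males
            pairs = [(f, males[rng.integers(len(males))]) for f in females]
    return pd.DataFrame(rows)


def g_test(counts) -> tuple[float, int, float]:
    """Likelihood-ratio G-test of homogeneity on a k x 2 table.

    G = 2 * sum O * ln(O / E) over cells with O > 0, with expectations
    from the row/column marginals and a chi-squared reference on k - 1
    degrees of freedom.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("counts must be a k x 2 table")
    if np.any(obs.sum(axis=1) <= 0):
        raise ValueError("every row must have a positive total")
    if np.any(obs.sum(axis=0) <= 0):
        raise ValueError("a column of the table is all zero")
    res = sps.chi2_contingency(obs, correction=False, lambda_="log-likelihood")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def sex_ratio_chisq(n_female: int, n_male: int) -> tuple[float, float]:
    """Chi-square test of observed sex counts against 50:50 (1 df):
    chi2 = (n_f - n_m)^2 / (n_f + n_m)."""
    total = n_female + n_male
    if total <= 0:
        raise ValueError("need at least one offspring")
    chi2 = (n_female - n_male) ** 2 / total
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def relative_density(
    cp_target_reps, cp_host_reps, sd_threshold: float = 2.5
) -> tuple[float, bool]:
    """qPCR relative density of a target against a host reference gene.

    Density is ``2 ** (mean Cp_host - mean Cp_target)`` over replicate
    runs; the QC flag is set when the replicate standard deviation of
    either marker exceeds ``sd_threshold``.
    """
    t = np.asarray(cp_target_reps, dtype=float)
    h = np.asarray(cp_host_reps, dtype=float)
    if t.size == 0 or h.size == 0:
        raise ValueError("need at least one Cp replicate per marker")
    density = float(2.0 ** (h.mean() - t.mean()))
    sd_t = float(t.std(ddof=1)) if t.size > 1 else 0.0
    sd_h = float(h.std(ddof=1)) if h.size > 1 else 0.0
    return density, bool(sd_t > sd_threshold or sd_h > sd_threshold)


def percent(k: int, n: int) -> float:
    """Percentage k/n at the 2-decimal resolution incidence tables print."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 2)


def incidence_table(site_counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-site and overall incidence of an affected class.

    ``site_counts`` maps site name -> (n_affected, n_total).  Returns
    per-site percentages plus an ``overall`` row, and attaches the G-test
    of homogeneity across sites as frame attrs (g, df, p).
    """
    rows = [
        {"site": site, "n_affected": k, "n_total": n, "pct": percent(k, n)}
        for site, (k, n) in site_counts.items()
    ]
    k_all = sum(k for k, _ in site_counts.values())
    n_all = sum(n for _, n in site_counts.values())
    rows.append({"site": "overall", "n_affected": k_all, "n_total": n_all,
                 "pct": percent(k_all, n_all)})
    df = pd.DataFrame(rows)
    g, dof, pval = g_test(
        [[k, n - k] for k, n in site_counts.values()]
    )
    df.attrs.update({"g": g, "df": dof, "p": pval})
    return df
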