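"""Synthetic CSF cohort generator.

Emulates the statistical structure of a middle-aged asymptomatic-AD study
cohort: three diagnosis groups (biomarker-negative cognitively normal
controls, biomarker-positive cognitively normal "AsymAD" cases, and
symptomatic biomarker-confirmed AD), a bimodal tTau:Abeta42 ratio across
the cohort, log-normal targeted-proteomics peptide abundances with a planted
informative subset, a latent Control-to-AD continuum for AsymAD cases,
Hardy-Weinberg APOE genotypes at group-specific epsilon-4 allele
frequencies, skew-noised cognitive scores loaded on tau, and
Abeta42-coupled comorbidity flags.

Every draw comes from a single :class:`numpy.random.Generator` seeded from
``CohortSpec.seed``, so identical specs produce byte-identical tables. The
ground truth (informative peptide set, latent positions, planted
coefficients) is returned alongside for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_CONTROL = "CN/BM-"
GROUP_ASYMAD = "AsymAD"
GROUP_AD = "AD"
GROUPS = (GROUP_CONTROL, GROUP_ASYMAD, GROUP_AD)

SUBGROUP_AD_LIKE = "AD-like"
SUBGROUP_CONTROL_LIKE = "Control-like"

ANALYTES = ("abeta42", "ttau", "ptau")

#: quartile z-score; log-normal with median m and quartiles (q1, q3) has
#: sigma = log(q3/q1) / (2 * 0.6745)
_Z75 = 0.674489750196082


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and quartiles."""
    if not (0 < q1 < median < q3):
        raise ValueError("need 0 < q1 < median < q3")
    return float(np.log(median)), float(np.log(q3 / q1) / (2 * _Z75))


# Per-group (median, q1, q3) in pg/ml for Abeta42, tTau, pTau.  These are
# typical Elecsys values for biomarker-negative controls, biomarker-positive
# cognitively normal cases, and symptomatic AD respectively, and are the
# generator's default calibration targets.
_ANALYTE_QUARTILES: dict[str, dict[str, tuple[float, float, float]]] = {
    GROUP_CONTROL: {
        "abeta42": (1412.0, 1192.0, 1700.0),
        "ttau": (167.6, 139.9, 192.7),
        "ptau": (14.8, 12.2, 17.2),
    },
    GROUP_ASYMAD: {
        "abeta42": (740.1, 609.8, 862.5),
        "ttau": (242.0, 194.9, 299.4),
        "ptau": (22.8, 18.6, 28.2),
    },
    GROUP_AD: {
        "abeta42": (540.7, 445.6, 660.2),
        "ttau": (343.2, 265.7, 458.5),
        "ptau": (33.9, 26.7, 47.3),
    },
}


def default_analyte_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group log-normal (mu, sigma) for each CSF analyte."""
    return {
        grp: {a: lognormal_from_quartiles(*_ANALYTE_QUARTILES[grp][a]) for a in ANALYTES}
        for grp in GROUPS
    }


def default_cognition_loadings() -> dict[str, dict[str, float]]:
    """Linear loadings of each cognitive score on standardized analytes.

    Visual-memory and visuospatial scores load on tau (tau-linked
    visuospatial decline); verbal list learning and Abeta42 loadings are
    null. Noise is right-skewed (shifted gamma, median 0); ``noise_shape`` /
    ``noise_scale`` parameterize it.
    """
    return {
        "moca": {"intercept": 26.8, "ttau": -0.25, "ptau": 0.0, "abeta42": 0.0,
                 "noise_shape": 2.0, "noise_scale": 1.0},
        "rcft_immediate": {"intercept": 17.0, "ttau": -0.9, "ptau": 0.0, "abeta42": 0.0,
                           "noise_shape": 2.0, "noise_scale": 2.0},
        "rcft_delayed": {"intercept": 16.0, "ttau": 0.0, "ptau": -0.6, "abeta42": 0.0,
                         "noise_shape": 2.0, "noise_scale": 2.0},
        "jolo": {"intercept": 25.5, "ttau": -0.35, "ptau": 0.0, "abeta42": 0.0,
                 "noise_shape": 2.0, "noise_scale": 1.2},
        "avlt_immediate": {"intercept": 9.5, "ttau": 0.0, "ptau": 0.0, "abeta42": 0.0,
                           "noise_shape": 2.0, "noise_scale": 1.5},
    }


def default_comorbidity_logits() -> dict[str, tuple[float, float]]:
    """(intercept, slope on standardized Abeta42) per comorbidity.

    Negative slopes make low-amyloid subjects more likely to carry the
    flag (dyslipidemia / diabetes coupling); hypertension is uncoupled.
    """
    return {
        "dyslipidemia": (0.1, -0.35),
        "diabetes": (-2.3, -0.45),
        "hypertension": (-0.7, 0.0),
    }


@dataclass
class CohortSpec:
    """Study-condition parameters for :func:`generate_cohort`.

    Defaults follow the reference study design: 134 subjects per group,
    75 peptides of which 8 carry a 2-SD log-scale shift between control
    and AD centroids, epsilon-4 allele frequencies 0.08 / 0.40 / 0.50, and
    analyte distributions calibrated to the group medians and IQRs above.
    """

    n_control: int = 134
    n_asymad: int = 134
    n_ad: int = 134
    n_peptides: int = 75
    informative_peptides: tuple[int, ...] = tuple(range(8))
    effect_sizes: tuple[float, ...] = (2.0,) * 8
    peptide_log_sigma: float = 1.0
    asymad_mix: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 5.0), (5.0, 2.0))
    asymad_mix_weight: float = 0.5
    apoe_e4_freq: Mapping[str, float] = field(
        default_factory=lambda: {GROUP_CONTROL: 0.08, GROUP_ASYMAD: 0.40, GROUP_AD: 0.50}
    )
    apoe_u_coupling: float = 0.6
    apoe_linked_peptides: tuple[int, int] | None = None
    apoe_allele_effect: float = 1.5
    analyte_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=default_analyte_params
    )
    tau_correlation: float = 0.9
    ratio_cutoff: float = 0.24
    cognition_loadings: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_cognition_loadings
    )
    comorbidity_logits: Mapping[str, tuple[float, float]] = field(
        default_factory=default_comorbidity_logits
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_asymad", "n_ad", "n_peptides"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.effect_sizes) != len(self.informative_peptides):
            raise ValueError("effect_sizes must align with informative_peptides")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect sizes must be finite")
        bad = [j for j in self.informative_peptides if not (0 <= j < self.n_peptides)]
        if bad:
            raise ValueError(f"informative peptide indices out of range: {bad}")
        for grp, f in self.apoe_e4_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"allele frequency for {grp} outside [0, 1]")
        if self.apoe_linked_peptides is not None:
            bad = [j for j in self.apoe_linked_peptides if not (0 <= j < self.n_peptides)]
            if bad:
                raise ValueError(f"APOE-linked peptide indices out of range: {bad}")
        if not (0.0 <= self.asymad_mix_weight <= 1.0):
            raise ValueError("asymad_mix_weight outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort (recovery-test oracle)."""

    informative_set: tuple[int, ...]
    u: pd.Series  # latent position, 0 for controls, 1 for AD
    true_subgroup: pd.Series  # AD-like iff u > 0.5 (AsymAD only, else NA)
    cognition_loadings: dict
    comorbidity_logits: dict
    protein_map: pd.Series  # peptide column -> protein id


def peptide_names(n: int) -> list[str]:
    return [f"pep{j:03d}" for j in range(n)]


def default_protein_map(n_peptides: int, n_proteins: int = 58) -> pd.Series:
    """Map peptides onto fewer proteins (some proteins yield two peptides)."""
    n_doubled = n_peptides - n_proteins
    if n_doubled < 0:
        n_proteins, n_doubled = n_peptides, 0
    prot = []
    for j in range(n_peptides):
        if j < 2 * n_doubled:
            prot.append(f"prot{j // 2:03d}")
        else:
            prot.append(f"prot{j - n_doubled:03d}")
    return pd.Series(prot, index=peptide_names(n_peptides), name="protein")


def _draw_analytes(rng, spec: CohortSpec, group: str, n: int, positive: bool) -> np.ndarray:
    """Draw (abeta42, ttau, ptau) rows; reject until the tTau:Abeta42 ratio
    is on the required side of the cutoff so the positive mixture component
    contains every AsymAD/AD subject."""
    p = spec.analyte_params[group]
    (mu_a, s_a), (mu_t, s_t), (mu_p, s_p) = p["abeta42"], p["ttau"], p["ptau"]
    rho = spec.tau_correlation
    out = np.empty((n, 3))
    todo = np.arange(n)
    for _ in range(1000):
        m = todo.size
        z_a = rng.standard_normal(m)
        z_t = rng.standard_normal(m)
        z_r = rng.standard_normal(m)
        abeta = np.exp(mu_a + s_a * z_a)
        ttau = np.exp(mu_t + s_t * z_t)
        ptau = np.exp(mu_p + s_p * (rho * z_t + np.sqrt(1 - rho**2) * z_r))
        ratio = ttau / abeta
        ok = (ratio > spec.ratio_cutoff) if positive else (ratio <= spec.ratio_cutoff)
        out[todo[ok]] = np.column_stack([abeta, ttau, ptau])[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError(
        f"analyte rejection sampling did not terminate for group {group}; "
        "check analyte_params against ratio_cutoff"
    )


def _draw_apoe(rng, freq: float, u: np.ndarray, coupling: float) -> tuple[np.ndarray, list[str]]:
    """Per-subject epsilon-4 allele counts and genotype strings.

    Allele probability is ``freq + coupling * (u - 0.5)`` clipped to (0, 1):
    mean-preserving in u, so the group frequency stays on target while
    subjects deeper along the AD continuum are epsilon-4 enriched.
    """
    p4 = np.clip(freq + coupling * (u - 0.5), 0.005, 0.995)
    alleles = rng.random((u.size, 2)) < p4[:, None]
    n_e4 = alleles.sum(axis=1)
    # non-e4 alleles are e3 with prob 0.9, e2 otherwise
    genos = []
    other = np.where(rng.random((u.size, 2)) < 0.9, "e3", "e2")
    for i in range(u.size):
        pair = sorted("e4" if alleles[i, k] else other[i, k] for k in range(2))
        genos.append("/".join(pair))
    return n_e4, genos


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (subject table, peptide abundance matrix, ground truth).

    Subjects are ordered control block, AsymAD block, AD block with ids
    ``S0000``... Peptide abundances are positive (log-normal); AsymAD
    log-abundance centroids interpolate linearly between the control and AD
    centroids at the subject's latent position ``u``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = {GROUP_CONTROL: spec.n_control, GROUP_ASYMAD: spec.n_asymad, GROUP_AD: spec.n_ad}
    n_total = sum(counts.values())
    ids = [f"S{i:04d}" for i in range(n_total)]
    group_col = np.repeat(list(counts), list(counts.values()))

    # latent continuum: controls at 0, AD at 1, AsymAD from a beta mixture
    n_asym = spec.n_asymad
    from_first = rng.random(n_asym) < spec.asymad_mix_weight
    (a1, b1), (a2, b2) = spec.asymad_mix
    u_asym = np.where(from_first, rng.beta(a1, b1, n_asym), rng.beta(a2, b2, n_asym))
    u = np.concatenate([np.zeros(spec.n_control), u_asym, np.ones(spec.n_ad)])

    # CSF analytes (rejection-sampled around the ratio cutoff, per group)
    blocks = [
        _draw_analytes(rng, spec, GROUP_CONTROL, spec.n_control, positive=False),
        _draw_analytes(rng, spec, GROUP_ASYMAD, spec.n_asymad, positive=True),
        _draw_analytes(rng, spec, GROUP_AD, spec.n_ad, positive=True),
    ]
    analytes = np.vstack(blocks)

    # APOE genotypes
    n_e4 = np.empty(n_total, dtype=int)
    genotype: list[str] = []
    start = 0
    for grp in GROUPS:
        n = counts[grp]
        sl = slice(start, start + n)
        coupling = spec.apoe_u_coupling if grp == GROUP_ASYMAD else 0.0
        cnt, genos = _draw_apoe(rng, spec.apoe_e4_freq[grp], u[sl], coupling)
        n_e4[sl] = cnt
        genotype.extend(genos)
        start += n

    # peptides: log-scale centroid interpolation + diagonal Gaussian noise
    mu_control = np.zeros(spec.n_peptides)
    mu_ad = np.zeros(spec.n_peptides)
    idx = np.asarray(spec.informative_peptides, dtype=int)
    if idx.size:
        mu_ad[idx] += np.asarray(spec.effect_sizes) * spec.peptide_log_sigma
    log_pep = ((1 - u)[:, None] * mu_control + u[:, None] * mu_ad
               + spec.peptide_log_sigma * rng.standard_normal((n_total, spec.n_peptides)))
    if spec.apoe_linked_peptides is not None:
        j_e4, j_e23 = spec.apoe_linked_peptides
        log_pep[:, j_e4] += spec.apoe_allele_effect * n_e4
        log_pep[:, j_e23] -= spec.apoe_allele_effect * n_e4
    peptides = pd.DataFrame(np.exp(log_pep), index=pd.Index(ids, name="subject_id"),
                            columns=peptide_names(spec.n_peptides))

    # demographics (groups drawn matched by construction)
    age = np.clip(rng.normal(66.0, 5.8, n_total), 50, 80).round(1)
    sex = np.where(rng.random(n_total) < 0.75, "F", "M")
    race = rng.choice(["Caucasian", "AfricanAmerican", "Asian"], size=n_total,
                      p=[0.925, 0.067, 0.008])
    educ = np.where(group_col == GROUP_AD,
                    rng.normal(15.4, 2.6, n_total), rng.normal(16.7, 2.1, n_total)).round(0)

    # cognitive scores: linear in standardized analytes + right-skewed noise
    z = {a: (np.log(analytes[:, k]) - np.log(analytes[:, k]).mean())
            / np.log(analytes[:, k]).std() for k, a in enumerate(ANALYTES)}
    scores = {}
    from scipy.stats import gamma as _gamma
    for name, load in spec.cognition_loadings.items():
        shape, scale = load["noise_shape"], load["noise_scale"]
        noise = rng.gamma(shape, scale, n_total) - _gamma.ppf(0.5, shape, scale=scale)
        scores[name] = (load["intercept"]
                        + load.get("ttau", 0.0) * z["ttau"]
                        + load.get("ptau", 0.0) * z["ptau"]
                        + load.get("abeta42", 0.0) * z["abeta42"]
                        - noise).round(2)

    # comorbidity flags: Bernoulli(logistic(intercept + slope * z_abeta42))
    comorbid = {}
    for name, (b0, b1) in spec.comorbidity_logits.items():
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * z["abeta42"])))
        comorbid[name] = (rng.random(n_total) < p).astype(int)
    # family history of AD, coupled to epsilon-4 dose
    p_fh = 1.0 / (1.0 + np.exp(-(-1.6 + 0.55 * n_e4)))
    fh_ad = (rng.random(n_total) < p_fh).astype(int)

    subjects = pd.DataFrame({
        "subject_id": ids,
        "group": group_col,
        "cognitively_normal": (group_col != GROUP_AD).astype(int),
        "age": age,
        "sex": sex,
        "race": race,
        "education": educ,
        "apoe": genotype,
        "apoe_e4_count": n_e4,
        "abeta42": analytes[:, 0].round(1),
        "ttau": analytes[:, 1].round(1),
        "ptau": analytes[:, 2].round(1),
        **scores,
        **comorbid,
        "family_history_ad": fh_ad,
    }).set_index("subject_id")

    subgroup = pd.Series(pd.NA, index=subjects.index, dtype="object", name="true_subgroup")
    asym_mask = subjects["group"] == GROUP_ASYMAD
    subgroup[asym_mask] = np.where(u[asym_mask.to_numpy()] > 0.5,
                                   SUBGROUP_AD_LIKE, SUBGROUP_CONTROL_LIKE)
    truth = GroundTruth(
        informative_set=tuple(int(j) for j in spec.informative_peptides),
        u=pd.Series(u, index=subjects.index, name="u"),
        true_subgroup=subgroup,
        cognition_loadings={k: dict(v) for k, v in spec.cognition_loadings.items()},
        comorbidity_logits={k: tuple(v) for k, v in spec.comorbidity_logits.items()},
        protein_map=default_protein_map(spec.n_peptides),
    )
    return subjects, peptides, truth


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (case_id, control_id)
    unmatched_cases: list[str]


def match_groups(
    subjects: pd.DataFrame,
    case_group: str,
    control_group: str,
    match_on: Sequence[str],
    caliper: Mapping[str, float] | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching of cases to controls.

    Categorical variables must match exactly; continuous variables must lie
    within their caliper (default: unlimited). Pairing is greedy on the
    globally smallest standardized L1 distance among eligible pairs, each
    control used at most once; ties break on (case, control) row order, so
    the pairing is deterministic. Unmatched cases are reported, not dropped
    silently.
    """
    caliper = dict(caliper or {})
    cases = subjects[subjects["group"] == case_group]
    controls = subjects[subjects["group"] == control_group]
    if cases.empty or controls.empty:
        raise ValueError("both groups must be non-empty")
    for v in match_on:
        if v not in subjects.columns:
            raise ValueError(f"match variable {v!r} missing from subject table")

    cont = [v for v in match_on if pd.api.types.is_numeric_dtype(subjects[v])]
    cat = [v for v in match_on if v not in cont]
    scale = {v: subjects[v].std() or 1.0 for v in cont}

    n_ca, n_co = len(cases), len(controls)
    dist = np.zeros((n_ca, n_co))
    elig = np.ones((n_ca, n_co), dtype=bool)
    for v in cat:
        elig &= cases[v].to_numpy()[:, None] == controls[v].to_numpy()[None, :]
    for v in cont:
        d = np.abs(cases[v].to_numpy()[:, None] - controls[v].to_numpy()[None, :])
        if v in caliper and np.isfinite(caliper[v]):
            elig &= d <= caliper[v]
        dist += d / scale[v]

    pairs: list[tuple[str, str]] = []
    dist = np.where(elig, dist, np.inf)
    work = dist.copy()
    for _ in range(min(n_ca, n_co)):
        i, j = np.unravel_index(np.argmin(work), work.shape)
        if not np.isfinite(work[i, j]):
            break
        pairs.append((cases.index[i], controls.index[j]))
        work[i, :] = np.inf
        work[:, j] = np.inf
    matched = {c for c, _ in pairs}
    unmatched = [c for c in cases.index if c not in matched]
    if unmatched:
        logger.warning("match_groups: %d unmatched case(s): %s", len(unmatched), unmatched)
    pairs.sort(key=lambda p: p[0])
    return MatchResult(pairs=pairs, unmatched_cases=unmatched)


def write_cohort(outdir, subjects: pd.DataFrame, peptides: pd.DataFrame,
                 truth: GroundTruth) -> None:
    """Write the cohort as UTF-8 CSVs (subject id as first column)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv")
    peptides.to_csv(out / "peptides.csv")
    gt = pd.DataFrame({"u": truth.u, "true_subgroup": truth.true_subgroup})
    gt.to_csv(out / "ground_truth.csv")
    truth.protein_map.rename_axis("peptide").to_csv(out / "protein_map.csv")
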