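"""Seeded synthetic datasets emulating the five-condition EGF time-course design.

The generator plants known structure so every downstream stage can be
tested for recovery:

* ``chronic_*`` genes shift baseline expression in one or both mutant
  lines (PTEN_KO, PIK3CA_H1047R) at all time points;
* ``egf_early_peak`` / ``egf_late_peak`` genes follow impulse-like EGF
  response profiles (peak at 15–40 min or 180–300 min) in every
  EGF-stimulated condition, independent of PI3K;
* ``pi3k_basal`` genes shift only in the A66-without-EGF arm;
* ``pi3k_induced`` genes respond to EGF but the response is attenuated by
  at least 75% under the PI3Kalpha inhibitor A66;
* ``coherent_up`` genes are up in both activating mutants and down under
  A66 (with or without EGF); ``coherent_down`` is the mirror image;
* a subset of motifs carries time/condition-varying activity that drives
  expression of its target genes through planted promoter site counts.

Counts are negative binomial with the mean–dispersion trend
``alpha(mu) = a/mu + b`` typical of bulk RNA-seq.  Each library's total is
rescaled to its drawn library size; the per-sample factor this introduces
is exactly what median-of-ratios size factors absorb.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from pip3scope.core_io import CONDITIONS, TIME_POINTS, Dataset, SampleMeta

CATEGORIES = (
    "null",
    "chronic_pten",
    "chronic_pik3ca",
    "chronic_both",
    "egf_early_peak",
    "egf_late_peak",
    "pi3k_basal",
    "pi3k_induced",
    "coherent_up",
    "coherent_down",
)

#: Default planted-category mix.  Proportions mirror the study's qualitative
#: findings at 4000 genes: chronic mutant effects remodel thousands of
#: mRNAs, acute PI3Kalpha perturbation affects hundreds, and only a small
#: coherent core (~3%) follows the directional PIP3 logic throughout.
DEFAULT_FRACTIONS = {
    "null": 0.51,
    "chronic_pten": 0.10,
    "chronic_pik3ca": 0.10,
    "chronic_both": 0.08,
    "egf_early_peak": 0.07,
    "egf_late_peak": 0.07,
    "pi3k_basal": 0.02,
    "pi3k_induced": 0.02,
    "coherent_up": 0.015,
    "coherent_down": 0.015,
}

# Impulse-like EGF response shapes (fraction of full effect per time point).
_EARLY_SHAPE = {0: 0.0, 15: 1.0, 40: 1.0, 90: 0.5, 180: 0.2, 300: 0.0}
_LATE_SHAPE = {0: 0.0, 15: 0.0, 40: 0.2, 90: 0.5, 180: 1.0, 300: 1.0}

#: Residual EGF response retained under A66 for pi3k_induced genes
#: (attenuation of at least 75%).
A66_RESIDUAL = 0.2


@dataclasses.dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic study.

    ``category_fractions`` must sum to 1; ``effect_log2fc`` is the planted
    effect magnitude in log2 units (default 2, i.e. four-fold).
    """

    n_genes: int = 4000
    seed: int = 0
    library_size_mean: float = 5e5
    library_size_cv: float = 0.1
    dispersion_a: float = 1.0
    dispersion_b: float = 0.05
    category_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    effect_log2fc: float = 2.0
    baseline_log2_sd: float = 1.0
    n_motifs: int = 20
    n_active_motifs: int = 4
    motif_activity_amplitude: float = 0.5
    promoters_per_gene_max: int = 2
    motif_target_fraction: float = 0.15
    background_site_rate: float = 0.5
    coupled_motif_category: str = "chronic_both"
    coupled_target_fraction: float = 0.6
    replicates: int = 3

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, expected 1")
        unknown = set(self.category_fractions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        for name in (
            "library_size_mean",
            "library_size_cv",
            "dispersion_a",
            "dispersion_b",
            "motif_activity_amplitude",
        ):
            if getattr(self, name) < 0 or (
                name == "library_size_mean" and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic Dataset.

    ``profiles`` holds the planted log2 effect (relative to the WT 0-min
    baseline, motif contribution excluded) per gene and condition:time
    group; ``motif_activity`` is the planted motifs x samples activity
    matrix in log2 units.
    """

    categories: pd.Series
    signs: pd.Series
    profiles: pd.DataFrame
    motif_activity: pd.DataFrame
    motif_sites: pd.DataFrame
    functional_sites: pd.DataFrame
    promoter_map: pd.Series
    driving_promoter: pd.Series
    active_motifs: list[str]

    def genes_in(self, *categories: str) -> set[str]:
        """Gene ids belonging to any of the given planted categories."""
        return set(self.categories.index[self.categories.isin(categories)])


def generate_design(
    replicates: int = 3, conditions=None, time_points=None
) -> list[SampleMeta]:
    """The study's sample layout: every condition at every EGF time point,
    except the no-EGF inhibitor arm which has a single 300-min group;
    triplicate libraries by default (25 groups, 75 samples)."""
    conditions = CONDITIONS if conditions is None else tuple(conditions)
    time_points = TIME_POINTS if time_points is None else tuple(time_points)
    samples = []
    for cond in conditions:
        times = (300,) if cond == "A66_noEGF" else time_points
        for t in times:
            if cond == "A66_noEGF" and t != 300:
                continue
            for r in range(1, replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{cond}_t{t}_r{r}",
                        condition=cond,
                        time_min=t,
                        replicate=r,
                    )
                )
    return samples


def _assign_categories(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic category counts by largest-remainder rounding, shuffled."""
    fracs = [cfg.category_fractions.get(c, 0.0) for c in CATEGORIES]
    exact = np.array(fracs) * cfg.n_genes
    counts = np.floor(exact).astype(int)
    remainder = cfg.n_genes - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.array(CATEGORIES, dtype=object), counts)
    rng.shuffle(labels)
    return labels


def _planted_profiles(
    categories: np.ndarray, signs: np.ndarray, effect: float, groups: list[tuple[str, int]]
) -> np.ndarray:
    """genes x groups matrix of planted log2 effects vs the WT 0-min baseline."""
    n = len(categories)
    prof = np.zeros((n, len(groups)))
    for j, (cond, t) in enumerate(groups):
        egf_stimulated = cond != "A66_noEGF"
        early = _EARLY_SHAPE[t] if egf_stimulated else 0.0
        late = _LATE_SHAPE[t] if egf_stimulated else 0.0
        for i in range(n):
            cat = categories[i]
            e = effect * signs[i]
            if cat == "chronic_pten" and cond == "PTEN_KO":
                prof[i, j] += e
            elif cat == "chronic_pik3ca" and cond == "PIK3CA_H1047R":
                prof[i, j] += e
            elif cat == "chronic_both" and cond in ("PTEN_KO", "PIK3CA_H1047R"):
                prof[i, j] += e
            elif cat == "egf_early_peak":
                prof[i, j] += e * early
            elif cat == "egf_late_peak":
                prof[i, j] += e * late
            elif cat == "pi3k_basal" and cond == "A66_noEGF":
                prof[i, j] += e
            elif cat == "pi3k_induced":
                if cond in ("WT", "PTEN_KO", "PIK3CA_H1047R"):
                    prof[i, j] += e * early
                elif cond == "A66":
                    prof[i, j] += e * early * A66_RESIDUAL
            elif cat == "coherent_up":
                if cond in ("PTEN_KO", "PIK3CA_H1047R"):
                    prof[i, j] += effect
                elif cond in ("A66", "A66_noEGF"):
                    prof[i, j] -= effect
            elif cat == "coherent_down":
                if cond in ("PTEN_KO", "PIK3CA_H1047R"):
                    prof[i, j] -= effect
                elif cond in ("A66", "A66_noEGF"):
                    prof[i, j] += effect
    return prof


def _planted_motifs(
    cfg: GeneratorConfig,
    gene_ids: list[str],
    categories: np.ndarray,
    samples: list[SampleMeta],
    rng: np.random.Generator,
):
    """Promoter site counts, promoter→gene map, and planted activities."""
    motif_names = [f"M{m:02d}" for m in range(cfg.n_motifs)]
    n_prom_per_gene = rng.integers(1, cfg.promoters_per_gene_max + 1, size=len(gene_ids))
    promoter_ids, gene_of_promoter, driving = [], [], {}
    for g, npr in zip(gene_ids, n_prom_per_gene):
        for k in range(npr):
            pid = f"{g}_p{k}"
            promoter_ids.append(pid)
            gene_of_promoter.append(g)
            if k == 0:
                driving[g] = pid
    background = rng.poisson(cfg.background_site_rate, size=(len(promoter_ids), cfg.n_motifs))
    functional = np.zeros_like(background)

    active = motif_names[: cfg.n_active_motifs]
    prom_index = {p: i for i, p in enumerate(promoter_ids)}
    coupled_mask = categories == cfg.coupled_motif_category
    # Genes whose planted logic depends on *absence* of an EGF time
    # response stay motif-free, so motif-driven (time-varying) expression
    # does not blur the acute-PI3K set assignments.
    eligible = ~np.isin(categories, ["pi3k_basal", "pi3k_induced"])
    # The first active motif is the dedicated regulator of the coupled
    # category (its strength-of-regulation scores separate the derived
    # gene sets); the remaining active motifs drive genes outside it.
    # Functional sites are shared by all of a target gene's promoters, so
    # every promoter row carries the regulatory content that explains the
    # gene-level expression assigned to it.
    prom_of_gene: dict[str, list[int]] = {}
    for p, g in zip(promoter_ids, gene_of_promoter):
        prom_of_gene.setdefault(g, []).append(prom_index[p])
    for j, m in enumerate(active):
        if j == 0 and coupled_mask.any():
            p_target = np.where(coupled_mask, cfg.coupled_target_fraction, 0.08)
        else:
            p_target = np.where(coupled_mask, 0.0, cfg.motif_target_fraction)
        is_target = (rng.random(len(gene_ids)) < p_target) & eligible
        extra = 1 + rng.poisson(1.5, size=int(is_target.sum()))
        for e, i in zip(extra, np.where(is_target)[0]):
            functional[prom_of_gene[gene_ids[i]], j] += e
    # the emitted site matrix is noisy evidence of regulation: functional
    # (expression-driving) sites plus non-functional background sites
    sites = background + functional

    # Activities are EGF-driven regulatory programs over the stimulation
    # time course, mutually orthogonal across active motifs so each motif
    # carries a distinct temporal signature; they are shared across
    # EGF-stimulated conditions and the no-EGF arm keeps the unstimulated
    # (t = 0) activity.  In log2 units.
    t_index = {t: i for i, t in enumerate(TIME_POINTS)}
    ortho, _ = np.linalg.qr(rng.normal(size=(len(TIME_POINTS), len(TIME_POINTS))))
    act = np.zeros((cfg.n_motifs, len(samples)))
    for j in range(cfg.n_active_motifs):
        prof = ortho[:, j] - ortho[0, j]  # anchored at the unstimulated state
        for s, meta in enumerate(samples):
            ti = 0 if meta.condition == "A66_noEGF" else t_index[meta.time_min]
            act[j, s] = prof[ti]
        span = act[j].max() - act[j].min()
        if span > 0:
            act[j] *= 2.0 / span  # unit peak-to-trough range before scaling
    act *= cfg.motif_activity_amplitude
    act -= act.mean(axis=1, keepdims=True)

    sites_df = pd.DataFrame(sites, index=promoter_ids, columns=motif_names)
    sites_df.index.name = "promoter_id"
    functional_df = pd.DataFrame(functional, index=promoter_ids, columns=motif_names)
    functional_df.index.name = "promoter_id"
    activity_df = pd.DataFrame(
        act, index=motif_names, columns=[s.sample_id for s in samples]
    )
    promoter_map = pd.Series(gene_of_promoter, index=promoter_ids, name="gene_id")
    driving_ser = pd.Series({g: driving[g] for g in gene_ids}, name="promoter_id")
    return sites_df, functional_df, promoter_map, driving_ser, activity_df, active


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a seeded synthetic Dataset plus its GroundTruth.

    Counts follow ``NB(mean=mu_gs, alpha=a/mu+b)`` with
    ``mu_gs = L_s * softmax(baseline + planted effects + motif term)``,
    so each library totals approximately its drawn size ``L_s``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = generate_design(replicates=cfg.replicates)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    categories = _assign_categories(cfg, rng)
    signs = np.where(rng.random(cfg.n_genes) < 0.5, 1.0, -1.0)

    groups = sorted({(s.condition, s.time_min) for s in samples})
    group_labels = [f"{c}:{t}" for c, t in groups]
    profiles = _planted_profiles(categories, signs, cfg.effect_log2fc, groups)
    group_of_sample = [groups.index((s.condition, s.time_min)) for s in samples]

    sites_df, functional_df, promoter_map, driving, activity_df, active = _planted_motifs(
        cfg, gene_ids, categories, samples, rng
    )
    # log2 motif contribution per gene via its driving promoter's
    # functional (expression-driving) site counts
    drive_sites = functional_df.loc[driving.loc[gene_ids].to_numpy()].to_numpy()
    motif_term = drive_sites @ activity_df.to_numpy()  # genes x samples

    baseline = rng.normal(0.0, cfg.baseline_log2_sd, size=cfg.n_genes)
    log2_expr = (
        baseline[:, None]
        + profiles[:, group_of_sample]
        + motif_term
    )
    rel = np.exp2(log2_expr)
    rel /= rel.sum(axis=0, keepdims=True)

    sigma = np.sqrt(np.log1p(cfg.library_size_cv**2))
    lib_sizes = cfg.library_size_mean * np.exp(
        rng.normal(0.0, sigma, size=len(samples)) - sigma**2 / 2
    )
    mu = rel * lib_sizes[None, :]
    mu = np.maximum(mu, 1e-8)
    alpha = cfg.dispersion_a / mu + cfg.dispersion_b
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=gene_ids, columns=[s.sample_id for s in samples]
    )
    counts_df.index.name = "gene_id"
    genes_df = pd.DataFrame(
        {
            "length_bp": rng.integers(500, 10_000, size=cfg.n_genes),
            "terms": [[] for _ in range(cfg.n_genes)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    dataset = Dataset(counts=counts_df, samples=samples, genes=genes_df)
    truth = GroundTruth(
        categories=pd.Series(categories, index=gene_ids, name="category"),
        signs=pd.Series(signs, index=gene_ids, name="sign"),
        profiles=pd.DataFrame(profiles, index=gene_ids, columns=group_labels),
        motif_activity=activity_df,
        motif_sites=sites_df,
        functional_sites=functional_df,
        promoter_map=promoter_map,
        driving_promoter=driving,
        active_motifs=active,
    )
    return dataset, truth


def generate_annotation(
    truth: GroundTruth,
    n_terms: int = 50,
    enrichment_odds: float = 20.0,
    seed: int = 0,
    background_prob: float = 0.05,
) -> tuple[pd.Series, dict[str, str]]:
    """Assign annotation terms with one designated term enriched per category.

    Background terms are assigned with probability ``background_prob``;
    each non-null category's designated term is drawn for its members with
    ``enrichment_odds`` times the background odds.  Returns the per-gene
    term lists and the category→designated-term map.
    """
    if enrichment_odds < 1:
        raise ValueError("enrichment_odds must be >= 1")
    rng = np.random.default_rng(seed)
    cats = [c for c in CATEGORIES if c != "null"]
    designated = {c: f"T{idx:03d}" for idx, c in enumerate(cats)}
    term_names = [f"T{idx:03d}" for idx in range(max(n_terms, len(cats)))]
    genes = list(truth.categories.index)
    odds_bg = background_prob / (1 - background_prob)
    p_enriched = (enrichment_odds * odds_bg) / (1 + enrichment_odds * odds_bg)
    draws = rng.random((len(genes), len(term_names)))
    annotation = {}
    for i, g in enumerate(genes):
        cat = truth.categories.iloc[i]
        terms = []
        for j, t in enumerate(term_names):
            p = background_prob
            if cat != "null" and designated[cat] == t:
                p = p_enriched
            if draws[i, j] < p:
                terms.append(t)
        annotation[g] = terms
    return pd.Series(annotation, name="terms"), designated


def write_truth(truth: GroundTruth, path) -> None:
    """Persist the planted per-gene category/sign table as TSV."""
    pd.DataFrame({"category": truth.categories, "sign": truth.signs}).rename_axis(
        "gene_id"
    ).to_csv(path, sep="\t")
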