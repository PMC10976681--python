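"""Synthetic multi-sample case/control cohorts with planted structure.

The generator produces sparse UMI counts with negative-binomial noise
(var = mu + phi * mu^2), per-sample shared activation scaling planted
per-cell-type differential programs, composition shifts, doublets,
sex-linked marker genes and mitochondrial fractions — everything the
downstream statistics assume, so each stage can be tested against a
known truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from pbmckit.containers import CellMatrix

N_MITO_GENES = 10
N_Y_GENES = 5
N_X_GENES = 5
MITO_PREFIX = "MT-"
Y_GENES = [f"Y-MARK{i + 1}" for i in range(N_Y_GENES)]
X_GENES = [f"X-MARK{i + 1}" for i in range(N_X_GENES)]

DEFAULT_CELL_TYPES = [
    "CD4_naive", "CD4_CM", "CD4_EM", "CD8_naive", "CD8_CM", "CD8_EM",
    "Treg", "MAIT", "NK", "B_naive", "B_SM", "C_mono", "NC_mono",
]
DEFAULT_COMPARTMENTS = {
    "CD4_naive": "TNK", "CD4_CM": "TNK", "CD4_EM": "TNK",
    "CD8_naive": "TNK", "CD8_CM": "TNK", "CD8_EM": "TNK",
    "Treg": "TNK", "MAIT": "TNK", "NK": "TNK",
    "B_naive": "B", "B_SM": "B",
    "C_mono": "Mono", "NC_mono": "Mono",
}


class ConfigurationError(ValueError):
    pass


@dataclass
class DeSpec:
    """Planted differential program for one cell type."""

    n_up: int = 0
    n_down: int = 0
    mean_abs_lfc: float = 1.0


@dataclass
class SimConfig:
    n_case: int = 10
    n_control: int = 10
    cell_types: List[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    abundance: Optional[List[float]] = None  # base fractions; uniform if None
    compartment_of: Optional[Dict[str, str]] = None
    genes: int = 2000
    n_feature_genes_per_type: int = 40
    de_spec: Dict[str, DeSpec] = field(default_factory=dict)
    activation_sd: float = 0.35  # sd of log alpha_s for cases
    composition_shift: Dict[str, float] = field(default_factory=dict)  # log-odds
    doublet_rate: float = 0.0
    mito_mean: float = 0.03
    mito_sd: float = 0.01
    dispersion: float = 0.2  # NB phi, scalar or per-gene array
    depth_mean: float = 1500.0
    cells_per_sample: int = 300
    dirichlet_concentration: float = 300.0
    marker_strength: float = 8.0  # fold elevation of a type's feature genes
    profile_jitter_sd: float = 0.25  # per-type lognormal jitter of non-marker genes
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0 or self.n_case + self.n_control < 1:
            raise ConfigurationError("need at least one sample")
        if self.genes <= 0 or self.cells_per_sample <= 0:
            raise ConfigurationError("non-positive dimensions")
        if self.abundance is None:
            k = len(self.cell_types)
            self.abundance = [1.0 / k] * k
        if len(self.abundance) != len(self.cell_types):
            raise ConfigurationError("abundance length must match cell_types")
        if abs(sum(self.abundance) - 1.0) > 1e-9:
            raise ConfigurationError("abundance fractions must sum to 1")
        if any(a < 0 for a in self.abundance):
            raise ConfigurationError("abundance fractions must be nonnegative")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ConfigurationError("doublet_rate must be in [0, 1)")
        if self.activation_sd < 0:
            raise ConfigurationError("activation_sd must be nonnegative")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ConfigurationError("dispersion must be positive")
        if self.compartment_of is None:
            if set(self.cell_types) <= set(DEFAULT_COMPARTMENTS):
                self.compartment_of = {
                    t: DEFAULT_COMPARTMENTS[t] for t in self.cell_types
                }
            else:
                self.compartment_of = {t: t for t in self.cell_types}
        for t, spec in self.de_spec.items():
            if t not in self.cell_types:
                raise ConfigurationError(f"de_spec for unknown cell type {t!r}")
            if spec.n_up < 0 or spec.n_down < 0:
                raise ConfigurationError("DE set sizes must be nonnegative")
        reserved = N_MITO_GENES + N_Y_GENES + N_X_GENES
        needed = reserved + len(self.cell_types) * self.n_feature_genes_per_type
        if self.genes < needed + 10:
            raise ConfigurationError(
                f"gene universe too small: {self.genes} < {needed + 10} "
                "(reserved + feature genes + slack)"
            )


@dataclass
class CohortTruth:
    """Ground truth accompanying a generated cohort."""

    samples: pd.DataFrame  # sample, disease, sex, batch, alpha, gada, hla_count
    composition: pd.DataFrame  # samples x cell types, true fractions
    de_sets: Dict[str, Dict[str, Dict[str, float]]]  # type -> {up/down -> {gene: lfc}}
    feature_genes: Dict[str, List[str]]
    profiles: pd.DataFrame  # cell types x genes expected relative expression
    gene_map: pd.DataFrame  # gene -> chrom, pos
    compartment_of: Dict[str, str]
    risk_genes: List[str] = field(default_factory=list)

    @property
    def cell_types(self) -> List[str]:
        return list(self.profiles.index)

    def up_down_sets(self) -> Dict[str, Dict[str, List[str]]]:
        return {
            t: {"up": sorted(s["up"]), "down": sorted(s["down"])}
            for t, s in self.de_sets.items()
        }


def _gene_names(n: int) -> List[str]:
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(N_MITO_GENES)]
    rest = n - N_MITO_GENES - N_Y_GENES - N_X_GENES
    return mito + Y_GENES + X_GENES + [f"G{i:05d}" for i in range(rest)]


def _gene_positions(names: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Assign genes uniformly to 22 autosomes with increasing positions.

    A slice of chromosome 6 between 25 and 35 Mb plays the role of the
    excludable MHC-like region downstream.
    """
    n = len(names)
    chroms = rng.integers(1, 23, size=n)
    pos = rng.integers(1, 150_000_000, size=n)
    df = pd.DataFrame({"chrom": chroms, "pos": pos}, index=pd.Index(names, name="gene"))
    df.loc[df.index.str.startswith(MITO_PREFIX), "chrom"] = 25  # MT pseudo-chrom
    df.loc[Y_GENES, "chrom"] = 24
    df.loc[X_GENES, "chrom"] = 23
    return df


def _make_profiles(config: SimConfig, rng: np.random.Generator):
    """Per-type expected relative expression over non-reserved genes."""
    names = _gene_names(config.genes)
    reserved = N_MITO_GENES + N_Y_GENES + N_X_GENES
    body = names[reserved:]
    n_body = len(body)
    base = rng.gamma(shape=0.6, scale=1.0, size=n_body) + 0.02
    feature_genes: Dict[str, List[str]] = {}
    profiles = {}
    start = 0
    for t in config.cell_types:
        prof = base * np.exp(rng.normal(0.0, config.profile_jitter_sd, size=n_body))
        block = slice(start, start + config.n_feature_genes_per_type)
        prof[block] *= config.marker_strength
        feature_genes[t] = list(body[block])
        start += config.n_feature_genes_per_type
        profiles[t] = prof / prof.sum()
    prof_df = pd.DataFrame(profiles, index=pd.Index(body, name="gene")).T
    return names, prof_df, feature_genes


def _plant_de(config: SimConfig, prof_df: pd.DataFrame,
              feature_genes: Dict[str, List[str]], rng: np.random.Generator):
    """Choose disjoint up/down gene sets per type with gamma-spread |lfc|."""
    body = list(prof_df.columns)
    reserved_markers = {g for gl in feature_genes.values() for g in gl}
    pool = [g for g in body if g not in reserved_markers]
    de_sets: Dict[str, Dict[str, Dict[str, float]]] = {}
    for t in config.cell_types:
        spec = config.de_spec.get(t, DeSpec())
        n_tot = spec.n_up + spec.n_down
        chosen = rng.choice(len(pool), size=n_tot, replace=False) if n_tot else []
        genes = [pool[i] for i in chosen]
        mags = rng.gamma(shape=6.0, scale=spec.mean_abs_lfc / 6.0, size=n_tot) \
            if n_tot else np.array([])
        up = {g: float(m) for g, m in zip(genes[: spec.n_up], mags[: spec.n_up])}
        down = {g: -float(m) for g, m in zip(genes[spec.n_up:], mags[spec.n_up:])}
        de_sets[t] = {"up": up, "down": down}
    return de_sets


def generate_cohort(config: SimConfig,
                    alpha_override: Optional[Sequence[float]] = None):
    """Generate a cohort; returns ``(CellMatrix, CohortTruth)``.

    Counts are NB with var = mu + phi mu^2 where mu is the depth-scaled
    type profile; in case samples the planted genes of each cell type
    are scaled by 2^(lfc * alpha_s) with alpha_s log-normal (mean ~1)
    shared across that sample's cell types. Controls have alpha_s = 0.
    ``alpha_override`` fixes the case samples' activation scalars (e.g.
    planted tiers) instead of drawing them.
    """
    rng = np.random.default_rng(config.seed)
    names, prof_df, feature_genes = _make_profiles(config, rng)
    de_sets = _plant_de(config, prof_df, feature_genes, rng)
    gene_map = _gene_positions(names, rng)

    n_samples = config.n_case + config.n_control
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    disease = np.array([1] * config.n_case + [0] * config.n_control)
    sex = rng.integers(0, 2, size=n_samples)  # 1 = male
    batch = np.array([f"B{i % config.n_batches + 1}" for i in range(n_samples)])
    alpha = np.where(
        disease == 1,
        np.exp(rng.normal(0.0, config.activation_sd, size=n_samples)),
        0.0,
    )
    if alpha_override is not None:
        if len(alpha_override) != config.n_case:
            raise ConfigurationError(
                "alpha_override must supply one value per case sample"
            )
        alpha[: config.n_case] = np.asarray(alpha_override, dtype=float)
    gada = np.where(
        disease == 1,
        50.0 * alpha * np.exp(rng.normal(0.0, 0.3, size=n_samples)),
        rng.uniform(0.0, 5.0, size=n_samples),
    )
    hla = np.where(
        disease == 1,
        rng.binomial(2, 0.6, size=n_samples),
        rng.binomial(2, 0.3, size=n_samples),
    )

    # per-sample composition from Dirichlet around (shifted) base fractions
    types = config.cell_types
    base_logit = np.log(np.maximum(config.abundance, 1e-12))
    shift = np.array([config.composition_shift.get(t, 0.0) for t in types])
    comp = np.empty((n_samples, len(types)))
    for s in range(n_samples):
        logits = base_logit + disease[s] * shift
        frac = np.exp(logits)
        frac /= frac.sum()
        comp[s] = rng.dirichlet(frac * config.dirichlet_concentration)

    body_cols = prof_df.columns
    type_idx = {t: i for i, t in enumerate(types)}
    prof_arr = prof_df.to_numpy()  # types x body genes
    phi = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (config.genes,))

    # fixed relative expression inside the reserved blocks
    mito_profile = rng.dirichlet(np.full(N_MITO_GENES, 5.0))
    y_profile = rng.dirichlet(np.full(N_Y_GENES, 5.0))
    x_profile = rng.dirichlet(np.full(N_X_GENES, 5.0))
    SEX_FRAC = 0.01

    blocks = []
    cell_rows = []
    for s in range(n_samples):
        n_cells = config.cells_per_sample
        cell_types_s = rng.choice(len(types), size=n_cells, p=comp[s])
        depth = config.depth_mean * np.exp(rng.normal(0.0, 0.3, size=n_cells))
        mito_frac = np.clip(
            rng.normal(config.mito_mean, config.mito_sd, size=n_cells), 0.0, 0.5
        )
        is_doublet = rng.random(n_cells) < config.doublet_rate
        partner = rng.integers(0, len(types), size=n_cells)

        # case-adjusted per-type body profiles for this sample
        adj = prof_arr.copy()
        if disease[s] == 1 and alpha[s] > 0:
            for t, sets in de_sets.items():
                ti = type_idx[t]
                for g, lfc in {**sets["up"], **sets["down"]}.items():
                    j = body_cols.get_loc(g)
                    adj[ti, j] *= 2.0 ** (lfc * alpha[s])
            adj /= adj.sum(axis=1, keepdims=True)

        body_prof = adj[cell_types_s]
        body_prof = np.where(
            is_doublet[:, None],
            0.5 * (adj[cell_types_s] + adj[partner]),
            body_prof,
        )
        eff_depth = np.where(is_doublet, 2.0 * depth, depth)

        y_frac = SEX_FRAC if sex[s] == 1 else 1e-5
        x_frac = SEX_FRAC * (2.0 if sex[s] == 0 else 1.0)
        body_frac = np.clip(1.0 - mito_frac - y_frac - x_frac, 0.0, 1.0)

        mu = np.empty((n_cells, config.genes))
        mu[:, :N_MITO_GENES] = np.outer(eff_depth * mito_frac, mito_profile)
        mu[:, N_MITO_GENES:N_MITO_GENES + N_Y_GENES] = np.outer(
            eff_depth * y_frac, y_profile
        )
        mu[:, N_MITO_GENES + N_Y_GENES:N_MITO_GENES + N_Y_GENES + N_X_GENES] = (
            np.outer(eff_depth * x_frac, x_profile)
        )
        mu[:, N_MITO_GENES + N_Y_GENES + N_X_GENES:] = (
            (eff_depth * body_frac)[:, None] * body_prof
        )

        lam = rng.gamma(1.0 / phi, phi * mu)  # gamma-Poisson mixture == NB
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        cell_rows.append(pd.DataFrame({
            "sample": sample_ids[s],
            "batch": batch[s],
            "disease": disease[s],
            "sex": sex[s],
            "doublet": is_doublet,
            "cell_type": [types[i] for i in cell_types_s],
            "mito_frac_true": mito_frac,
        }))

    X = sp.vstack(blocks, format="csr")
    cells = pd.concat(cell_rows, ignore_index=True)
    cells.index = pd.Index(
        [f"CELL{i:06d}" for i in range(len(cells))], name="barcode"
    )
    genes = gene_map.copy()
    cm = CellMatrix(X, cells, genes)
    truth = CohortTruth(
        samples=pd.DataFrame({
            "sample": sample_ids, "disease": disease, "sex": sex,
            "batch": batch, "alpha": alpha, "gada": gada, "hla_count": hla,
        }).set_index("sample"),
        composition=pd.DataFrame(comp, index=sample_ids, columns=types),
        de_sets=de_sets,
        feature_genes=feature_genes,
        profiles=prof_df,
        gene_map=gene_map,
        compartment_of=dict(config.compartment_of),
    )
    return cm, truth


def generate_reference_panel(truth: CohortTruth, noise_sd: float = 0.0,
                             types: Optional[Sequence[str]] = None,
                             by_compartment: bool = False,
                             name: str = "panel", seed: int = 0):
    """Reference panel: log10 expected profiles over the types' feature genes.

    ``by_compartment`` aggregates member types into one row per
    compartment (the major panel of a hierarchy); otherwise one row per
    cell type. Gaussian noise of sd ``noise_sd`` is added to the log10
    values.
    """
    from pbmckit.project import ReferencePanel

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if types is None:
        types = truth.cell_types
    if by_compartment:
        comps: Dict[str, List[str]] = {}
        for t in types:
            comps.setdefault(truth.compartment_of[t], []).append(t)
        rows = {
            c: truth.profiles.loc[members].mean(axis=0)
            for c, members in comps.items()
        }
        row_df = pd.DataFrame(rows).T
        feat = sorted({g for t in types for g in truth.feature_genes[t]})
        parent = None
    else:
        row_df = truth.profiles.loc[list(types)]
        feat = sorted({g for t in types for g in truth.feature_genes[t]})
        parent = {t: truth.compartment_of[t] for t in types}
    mat = row_df[feat] * 1e4  # scale to counts-per-10k before log10
    vals = np.log10(mat.to_numpy() + 1e-2)
    vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return ReferencePanel(
        name=name,
        matrix=pd.DataFrame(vals, index=mat.index, columns=mat.columns),
        parent_compartment=parent,
    )


def generate_panel_hierarchy(truth: CohortTruth, noise_sd: float = 0.0,
                             seed: int = 0):
    """(major panel, {compartment: [subpanel]}) for multiresolution annotation."""
    major = generate_reference_panel(
        truth, noise_sd, by_compartment=True, name="major", seed=seed
    )
    subpanels: Dict[str, list] = {}
    comps: Dict[str, List[str]] = {}
    for t in truth.cell_types:
        comps.setdefault(truth.compartment_of[t], []).append(t)
    for i, (c, members) in enumerate(sorted(comps.items())):
        if len(members) > 1:
            subpanels[c] = [generate_reference_panel(
                truth, noise_sd, types=members, name=f"sub_{c}", seed=seed + i + 1
            )]
    return major, subpanels


def generate_gene_risk_scores(truth: CohortTruth, signal_frac: float,
                              causal_types: Optional[Sequence[str]] = None,
                              effect: float = 3.0, seed: int = 0) -> pd.DataFrame:
    """Gene-level risk score table (gene, score, chrom, pos).

    Scores are nonnegative (-log10 p style, Exponential(1) baseline);
    a fraction ``signal_frac`` of the planted DE genes of
    ``causal_types`` get an additive elevation of mean ``effect``
    scaled by the gene's planted |log2FC| (stronger programs carry
    more risk, which is what the downstream covariate test measures).
    Records the elevated genes in ``truth.risk_genes``.
    """
    if not 0.0 <= signal_frac <= 1.0:
        raise ValueError("signal_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.gene_map.index
    score = rng.exponential(1.0, size=len(genes))
    risk_genes: List[str] = []
    if signal_frac > 0 and causal_types:
        cand_lfc: Dict[str, float] = {}
        for t in causal_types:
            for d in ("up", "down"):
                for g, l in truth.de_sets.get(t, {}).get(d, {}).items():
                    cand_lfc[g] = max(cand_lfc.get(g, 0.0), abs(l))
        cand = sorted(cand_lfc)
        n_sig = int(round(signal_frac * len(cand)))
        if n_sig:
            pick = rng.choice(len(cand), size=n_sig, replace=False)
            risk_genes = [cand[i] for i in pick]
            loc = genes.get_indexer(risk_genes)
            mean_lfc = np.mean([cand_lfc[g] for g in risk_genes]) or 1.0
            weights = np.array([cand_lfc[g] for g in risk_genes]) / mean_lfc
            score[loc] += rng.gamma(4.0, effect / 4.0, size=n_sig) * weights
    truth.risk_genes = risk_genes
    return pd.DataFrame({
        "gene": genes,
        "score": score,
        "chrom": truth.gene_map["chrom"].to_numpy(),
        "pos": truth.gene_map["pos"].to_numpy(),
    }).set_index("gene")


def balanced_abundance(cell_types: Sequence[str],
                       compartment_of: Dict[str, str]) -> List[float]:
    """Fractions giving each compartment equal total abundance.

    Row-z projection scores saturate for a dominant compartment (the
    z-transform centers across cells), so annotation demos and default
    pipeline cohorts use compartment-balanced composition.
    """
    comps: Dict[str, int] = {}
    for t in cell_types:
        comps[compartment_of[t]] = comps.get(compartment_of[t], 0) + 1
    n_comp = len(comps)
    return [1.0 / (n_comp * comps[compartment_of[t]]) for t in cell_types]


def default_de_spec(cell_types: Sequence[str], n_up: int = 60, n_down: int = 40,
                    mean_abs_lfc: float = 1.0) -> Dict[str, DeSpec]:
    return {t: DeSpec(n_up, n_down, mean_abs_lfc) for t in cell_types}
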