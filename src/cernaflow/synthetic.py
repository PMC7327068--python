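"""Ground-truthed synthetic multi-omic data generator.

Emulates the five-group rat renal-interstitial-fibrosis treatment design
(NC normal control, OC untreated model control, LK/HK low/high-dose herbal
treatment, LOS losartan) across three RNA layers (mRNA, miRNA, lncRNA), plus
the accompanying histology grades, qPCR Ct tables, predicted miRNA-target
map, and pathway gene sets. Every planted effect is recorded in a
:class:`GroundTruthManifest` so recovery can be tested.

Generative model
----------------
Counts are negative-binomial (gamma-Poisson) around per-feature, per-sample
means: ``variance = mu + dispersion * mu^2``. Feature baselines are
log-normal around ``baseline_mean``. Treatment responsiveness follows a dose
profile: a per-group multiplier on the planted effect with NC = 0 and OC = 1,
and the high-dose group closest to normal — giving a monotone severity axis.

Planted structure is driven by a per-sample latent regulator ``z``: the
standardized dose of the sample's group plus a small independent jitter.
A planted repression pair puts ``+tau*z`` on the miRNA's log2 mean and
``-tau*(sqrt(c)*z + sqrt(1-c)*noise)`` on its target, so the sample-wise
Pearson correlation concentrates near ``-sqrt(c)`` (``c`` =
``repression_coupling``, the fraction of target variance explained by the
miRNA). A sponge lncRNA loads ``-tau*z`` (plus small noise): negatively
correlated with its miRNA, positively with the miRNA's target — the ceRNA
sign pattern. Decoy target-map entries pair miRNAs with inert genes so the
map filter is testably non-vacuous.

One master seed spawns independent child streams per layer, so adding or
resizing one layer never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import (
    GRADE_COLUMNS,
    N_GLOMERULI,
    ExpressionMatrix,
    HistologyTables,
    PathwaySets,
    TargetMap,
    write_ct_table,
    write_expression,
    write_gmt,
    write_histology,
    write_target_map,
)

__all__ = [
    "GROUPS",
    "DEFAULT_DOSE_PROFILE",
    "SimulationConfig",
    "GroundTruthManifest",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_histology",
    "simulate_ct_table",
    "write_dataset",
]

GROUPS = ("NC", "OC", "LK", "HK", "LOS")

#: Per-group multiplier on every planted effect. NC carries none of the
#: disease effect, OC all of it; high-dose treatment (HK) ends nearest NC,
#: losartan between the two herbal doses.
DEFAULT_DOSE_PROFILE = {"NC": 0.0, "OC": 1.0, "LK": 0.7, "HK": 0.2, "LOS": 0.4}

# qPCR panel: fibrosis markers rise with disease severity, the
# anti-fibrotic targets fall; log2 effect size at full dose.
CT_GENES_UP = ("Tgfb1", "Smad3", "Col1a1", "Col1a2", "Fn1", "Acta2")
CT_GENES_DOWN = ("Smad7", "Tmlhe")
CT_REFERENCE_GENE = "Gapdh"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic five-group, three-layer experiment.

    Defaults are the study conditions the analysis stages are tested under:
    3 animals per group with RNA profiles, |log2 fold change| 2 for planted
    treatment-responsive mRNAs, repression coupling near 1 (pair
    correlations concentrate near -sqrt(coupling)), NB dispersion 0.12 at a
    baseline of ~1000 counts (animal-to-animal biological variability large
    enough that a significant t-test at n = 3 already implies a >1.5-fold
    change, keeping the DEG rule's null rate at the t-test's type-I level).
    Pair/sponge ("structural") features sit at a fixed mid-range baseline
    with low dispersion — dispersion heterogeneity across genes is the norm
    in bulk RNA-seq — so their latent swing neither drowns in count noise
    nor dominates library sizes (which would distort every other feature's
    CPM through the compositional normalization).
    """

    n_per_group: int = 3
    n_mrna: int = 600
    n_mirna: int = 150
    n_lncrna: int = 200
    baseline_mean: float = 1000.0
    baseline_log2_sd: float = 1.0
    baseline_floor: float = 50.0
    nb_dispersion: float = 0.12
    n_de_mrna: int = 60
    effect_log2fc: float = 2.0
    dose_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_PROFILE)
    )
    n_true_mirna_pairs: int = 15
    repression_coupling: float = 0.99
    pair_latent_sd: float = 2.5
    latent_dose_jitter: float = 0.3
    n_sponge_triads: int = 5
    sponge_noise_sd: float = 0.3
    structural_baseline: float = 300.0
    structural_dispersion: float = 0.03
    decoy_target_fraction: float = 0.5
    n_pathways: int = 20
    pathway_size: int = 20
    n_planted_enriched: int = 1
    pathway_de_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        for name in ("n_mrna", "n_mirna", "n_lncrna"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "n_de_mrna",
            "n_true_mirna_pairs",
            "n_sponge_triads",
            "n_pathways",
            "n_planted_enriched",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.nb_dispersion < 0 or self.structural_dispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        if self.structural_baseline <= 0:
            raise ConfigError("structural_baseline must be > 0")
        if not 0 <= self.repression_coupling <= 1:
            raise ConfigError("repression_coupling must lie in [0, 1]")
        if not 0 <= self.decoy_target_fraction < 1:
            raise ConfigError("decoy_target_fraction must lie in [0, 1)")
        if set(self.dose_profile) != set(GROUPS):
            raise ConfigError(f"dose_profile must cover exactly the groups {GROUPS}")
        if self.dose_profile["NC"] != 0:
            raise ConfigError("dose_profile['NC'] must be 0 (no effect in normal control)")
        if self.baseline_mean <= 0 or self.baseline_floor <= 0:
            raise ConfigError("baseline parameters must be > 0")
        n_structural = self.n_de_mrna + self.n_true_mirna_pairs + self.n_decoy_targets
        if n_structural > self.n_mrna:
            raise ConfigError(
                f"planted mRNA structure ({n_structural}) exceeds n_mrna ({self.n_mrna})"
            )
        if self.n_true_mirna_pairs > self.n_mirna:
            raise ConfigError("n_true_mirna_pairs exceeds n_mirna")
        if self.n_sponge_triads > self.n_true_mirna_pairs:
            raise ConfigError("n_sponge_triads exceeds n_true_mirna_pairs")
        if self.n_sponge_triads > self.n_lncrna:
            raise ConfigError("n_sponge_triads exceeds n_lncrna")
        if self.n_planted_enriched > self.n_pathways:
            raise ConfigError("n_planted_enriched exceeds n_pathways")
        if self.pathway_size < 1 or self.pathway_size > self.n_mrna:
            raise ConfigError("pathway_size must lie in [1, n_mrna]")

    @property
    def n_decoy_targets(self) -> int:
        f = self.decoy_target_fraction
        return int(round(self.n_true_mirna_pairs * f / (1 - f)))

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in GROUPS for i in range(self.n_per_group)]

    @property
    def design(self) -> pd.Series:
        ser = pd.Series(
            {s: s.rsplit("_", 1)[0] for s in self.samples}, name="group"
        )
        ser.index.name = "sample"
        return ser

    def dose_vector(self) -> np.ndarray:
        return np.array([self.dose_profile[g] for g in self.design], dtype=float)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class GroundTruthManifest:
    """Record of every planted effect, used by recovery tests.

    ``de_features`` maps layer -> {feature: direction} with direction the
    sign of the feature in the disease model (OC) relative to normal (NC).
    ``group_means`` stores the deterministic per-feature expected count for
    each group (pair features: expectation at the group's dose with zero
    latent jitter).
    """

    de_features: dict[str, dict[str, str]]
    true_mirna_pairs: list[tuple[str, str]]
    sponge_triads: list[tuple[str, str, str]]
    decoy_pairs: list[tuple[str, str]]
    enriched_pathways: list[str]
    group_means: dict[str, dict[str, dict[str, float]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_features": self.de_features,
            "true_mirna_pairs": [list(p) for p in self.true_mirna_pairs],
            "sponge_triads": [list(t) for t in self.sponge_triads],
            "decoy_pairs": [list(p) for p in self.decoy_pairs],
            "enriched_pathways": list(self.enriched_pathways),
            "group_means": self.group_means,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            de_features=d["de_features"],
            true_mirna_pairs=[tuple(p) for p in d["true_mirna_pairs"]],
            sponge_triads=[tuple(t) for t in d["sponge_triads"]],
            decoy_pairs=[tuple(p) for p in d["decoy_pairs"]],
            enriched_pathways=list(d["enriched_pathways"]),
            group_means=d["group_means"],
        )


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulated experiment produces."""

    config: SimulationConfig
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    target_map: TargetMap
    pathways: PathwaySets
    histology: HistologyTables
    ct_table: pd.DataFrame
    manifest: GroundTruthManifest

    @property
    def layers(self) -> dict[str, ExpressionMatrix]:
        return {"mRNA": self.mrna, "miRNA": self.mirna, "lncRNA": self.lncrna}


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float | np.ndarray
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (gamma-Poisson).

    ``dispersion`` may be a scalar or a per-feature (row) vector; zero
    dispersion degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    disp = np.broadcast_to(
        np.asarray(dispersion, dtype=float).reshape(-1, 1)
        if np.ndim(dispersion) == 1
        else np.asarray(dispersion, dtype=float),
        mu.shape,
    )
    lam = np.where(
        disp > 0,
        rng.gamma(shape=1.0 / np.where(disp > 0, disp, 1.0), scale=mu * disp),
        mu,
    )
    return rng.poisson(lam)


def _feature_baselines(
    rng: np.random.Generator, n: int, cfg: SimulationConfig
) -> np.ndarray:
    base = cfg.baseline_mean * 2.0 ** rng.normal(0.0, cfg.baseline_log2_sd, size=n)
    return np.maximum(base, cfg.baseline_floor)


def _standardized_dose(cfg: SimulationConfig) -> np.ndarray:
    d = cfg.dose_vector()
    sd = d.std()
    if sd == 0:
        return np.zeros_like(d)
    return (d - d.mean()) / sd


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one complete synthetic experiment.

    Identical configs (including seed) give byte-identical outputs. Raises
    :class:`~cernaflow.errors.ConfigError` when planted set sizes exceed
    feature counts (validated on the config itself).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (
        ss_latent,
        ss_mrna,
        ss_mirna,
        ss_lnc,
        ss_map,
        ss_path,
        ss_hist,
        ss_ct,
    ) = ss.spawn(8)
    rng_latent = np.random.default_rng(ss_latent)
    rng_mrna = np.random.default_rng(ss_mrna)
    rng_mirna = np.random.default_rng(ss_mirna)
    rng_lnc = np.random.default_rng(ss_lnc)

    samples = cfg.samples
    design = cfg.design
    n_s = len(samples)
    dose = cfg.dose_vector()
    zdose = _standardized_dose(cfg)

    n_pairs = cfg.n_true_mirna_pairs
    tau = cfg.pair_latent_sd
    c = cfg.repression_coupling
    jit = cfg.latent_dose_jitter

    # latent regulator per planted pair per sample, plus target/sponge noise
    z = zdose[None, :] + jit * rng_latent.normal(size=(n_pairs, n_s))
    eps_target = rng_latent.normal(size=(n_pairs, n_s))
    eps_sponge = rng_latent.normal(size=(cfg.n_sponge_triads, n_s))

    # ---- feature ids and planted roles
    mrna_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_mrna)]
    mirna_ids = [f"mir{i + 1:04d}" for i in range(cfg.n_mirna)]
    lnc_ids = [f"lnc{i + 1:04d}" for i in range(cfg.n_lncrna)]

    de_idx = list(range(cfg.n_de_mrna))
    de_dirs = np.array([1 if i % 2 == 0 else -1 for i in de_idx])
    pair_target_idx = list(range(cfg.n_de_mrna, cfg.n_de_mrna + n_pairs))
    decoy_target_idx = list(
        range(
            cfg.n_de_mrna + n_pairs,
            cfg.n_de_mrna + n_pairs + cfg.n_decoy_targets,
        )
    )
    pair_mirna_idx = list(range(n_pairs))
    sponge_lnc_idx = list(range(cfg.n_sponge_triads))

    # ---- log2 mean matrices
    def _expected_log2(base: np.ndarray) -> np.ndarray:
        return np.tile(np.log2(base)[:, None], (1, n_s))

    base_mrna = _feature_baselines(rng_mrna, cfg.n_mrna, cfg)
    base_mrna[pair_target_idx] = cfg.structural_baseline
    log2_mrna = _expected_log2(base_mrna)
    if de_idx:
        log2_mrna[de_idx, :] += de_dirs[:, None] * cfg.effect_log2fc * dose[None, :]
    if pair_target_idx:
        log2_mrna[pair_target_idx, :] -= tau * (
            np.sqrt(c) * z + np.sqrt(1.0 - c) * eps_target
        )
    disp_mrna = np.full(cfg.n_mrna, cfg.nb_dispersion)
    disp_mrna[pair_target_idx] = cfg.structural_dispersion

    base_mirna = _feature_baselines(rng_mirna, cfg.n_mirna, cfg)
    base_mirna[pair_mirna_idx] = cfg.structural_baseline
    log2_mirna = _expected_log2(base_mirna)
    if pair_mirna_idx:
        log2_mirna[pair_mirna_idx, :] += tau * z
    disp_mirna = np.full(cfg.n_mirna, cfg.nb_dispersion)
    disp_mirna[pair_mirna_idx] = cfg.structural_dispersion

    base_lnc = _feature_baselines(rng_lnc, cfg.n_lncrna, cfg)
    base_lnc[sponge_lnc_idx] = cfg.structural_baseline
    log2_lnc = _expected_log2(base_lnc)
    if sponge_lnc_idx:
        log2_lnc[sponge_lnc_idx, :] += (
            -tau * z[: cfg.n_sponge_triads, :] + cfg.sponge_noise_sd * eps_sponge
        )
    disp_lnc = np.full(cfg.n_lncrna, cfg.nb_dispersion)
    disp_lnc[sponge_lnc_idx] = cfg.structural_dispersion

    def _matrix(rng, log2_mu, disp, ids, layer) -> ExpressionMatrix:
        counts = _nb_counts(rng, 2.0**log2_mu, disp)
        values = pd.DataFrame(counts, index=ids, columns=samples)
        values.index.name = "feature_id"
        return ExpressionMatrix(layer=layer, values=values, design=design.copy())

    mrna = _matrix(rng_mrna, log2_mrna, disp_mrna, mrna_ids, "mRNA")
    mirna = _matrix(rng_mirna, log2_mirna, disp_mirna, mirna_ids, "miRNA")
    lncrna = _matrix(rng_lnc, log2_lnc, disp_lnc, lnc_ids, "lncRNA")

    # ---- target map: true repression pairs + decoys on inert genes
    rng_map = np.random.default_rng(ss_map)
    true_pairs = [
        (mirna_ids[pair_mirna_idx[j]], mrna_ids[pair_target_idx[j]])
        for j in range(n_pairs)
    ]
    decoy_mirnas = (
        rng_map.choice(cfg.n_mirna, size=len(decoy_target_idx), replace=True)
        if decoy_target_idx
        else np.array([], dtype=int)
    )
    decoy_pairs = [
        (mirna_ids[int(mi)], mrna_ids[gi])
        for mi, gi in zip(decoy_mirnas, decoy_target_idx)
    ]
    target_map = TargetMap.from_pairs(
        [(m, t, "mRNA") for m, t in true_pairs + decoy_pairs]
    )

    # ---- pathway sets: planted enriched pathway(s) packed with DE genes
    rng_path = np.random.default_rng(ss_path)
    null_pool = [
        mrna_ids[i]
        for i in range(cfg.n_mrna)
        if i not in set(de_idx) | set(pair_target_idx)
    ]
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    enriched_names = []
    n_de_members = min(
        int(round(cfg.pathway_de_fraction * cfg.pathway_size)), cfg.n_de_mrna
    )
    for p in range(cfg.n_pathways):
        name = f"PATH{p + 1:03d}"
        if p < cfg.n_planted_enriched and n_de_members > 0:
            de_members = rng_path.choice(
                cfg.n_de_mrna, size=n_de_members, replace=False
            )
            fillers = rng_path.choice(
                len(null_pool), size=cfg.pathway_size - n_de_members, replace=False
            )
            genes = [mrna_ids[i] for i in de_members] + [null_pool[i] for i in fillers]
            descriptions[name] = "synthetic planted enriched pathway"
            enriched_names.append(name)
        else:
            members = rng_path.choice(cfg.n_mrna, size=cfg.pathway_size, replace=False)
            genes = [mrna_ids[i] for i in members]
            descriptions[name] = "synthetic background pathway"
        sets[name] = genes
    pathways = PathwaySets(sets=sets, descriptions=descriptions)

    # ---- histology and qPCR
    histology = simulate_histology(cfg, rng=np.random.default_rng(ss_hist))
    ct_table = simulate_ct_table(cfg, rng=np.random.default_rng(ss_ct))

    # ---- ground truth manifest
    de_features = {
        "mRNA": {
            **{
                mrna_ids[i]: ("up" if d > 0 else "down")
                for i, d in zip(de_idx, de_dirs)
            },
            **{mrna_ids[i]: "down" for i in pair_target_idx},
        },
        "miRNA": {mirna_ids[i]: "up" for i in pair_mirna_idx},
        "lncRNA": {lnc_ids[i]: "down" for i in sponge_lnc_idx},
    }
    sponge_triads = [
        (lnc_ids[sponge_lnc_idx[j]], *true_pairs[j])
        for j in range(cfg.n_sponge_triads)
    ]

    group_dose = {g: cfg.dose_profile[g] for g in GROUPS}
    zd_by_group = {
        g: float(zdose[list(design).index(g)]) if g in set(design) else 0.0
        for g in GROUPS
    }

    # expected per-group means with latent jitter and noise at zero
    def _expected_means(ids, base, shift_fn) -> dict[str, dict[str, float]]:
        out = {}
        for i, fid in enumerate(ids):
            out[fid] = {
                g: float(base[i] * 2.0 ** shift_fn(i, g)) for g in GROUPS
            }
        return out

    def _mrna_shift(i: int, g: str) -> float:
        if i in set(de_idx):
            d = de_dirs[de_idx.index(i)]
            return float(d * cfg.effect_log2fc * group_dose[g])
        if i in set(pair_target_idx):
            return float(-tau * np.sqrt(c) * zd_by_group[g])
        return 0.0

    def _mirna_shift(i: int, g: str) -> float:
        if i in set(pair_mirna_idx):
            return float(tau * zd_by_group[g])
        return 0.0

    def _lnc_shift(i: int, g: str) -> float:
        if i in set(sponge_lnc_idx):
            return float(-tau * zd_by_group[g])
        return 0.0

    group_means = {
        "mRNA": _expected_means(mrna_ids, base_mrna, _mrna_shift),
        "miRNA": _expected_means(mirna_ids, base_mirna, _mirna_shift),
        "lncRNA": _expected_means(lnc_ids, base_lnc, _lnc_shift),
    }

    manifest = GroundTruthManifest(
        de_features=de_features,
        true_mirna_pairs=true_pairs,
        sponge_triads=sponge_triads,
        decoy_pairs=decoy_pairs,
        enriched_pathways=enriched_names,
        group_means=group_means,
    )

    return SimulatedDataset(
        config=cfg,
        mrna=mrna,
        mirna=mirna,
        lncrna=lncrna,
        target_map=target_map,
        pathways=pathways,
        histology=histology,
        ct_table=ct_table,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------


def default_grade_probabilities(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-group glomerulus grade distributions.

    Each glomerulus grade is Binomial(4, p) with p rising with the group's
    dose multiplier (0.05 at normal, 0.90 at full disease), so expected GSI
    is 4p and group ordering follows the dose profile.
    """
    out = {}
    for g in GROUPS:
        p = 0.05 + 0.85 * cfg.dose_profile[g]
        out[g] = stats.binom.pmf(np.arange(5), 4, p)
    return out


def simulate_histology(
    config: SimulationConfig,
    grade_probs: Mapping[str, Sequence[float]] | None = None,
    injury_mean: Mapping[str, float] | None = None,
    injury_sd: float = 5.0,
    rng: np.random.Generator | None = None,
) -> HistologyTables:
    """Per-animal glomerulus grades (40 each) and injury/fibrosis percentages.

    ``grade_probs`` maps group -> probability vector over grades 0-4 (must
    sum to 1); defaults follow the dose profile. ``injury_mean`` maps group
    -> expected percent injured tubulointerstitial area.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[6])
    if grade_probs is None:
        grade_probs = default_grade_probabilities(cfg)
    probs = {}
    for g in GROUPS:
        vec = np.asarray(grade_probs[g], dtype=float)
        if vec.shape != (5,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-8:
            raise ConfigError(
                f"grade probabilities for group {g!r} must be 5 non-negative values summing to 1"
            )
        probs[g] = vec
    if injury_mean is None:
        injury_mean = {g: 5.0 + 75.0 * cfg.dose_profile[g] for g in GROUPS}

    glom_rows, tub_rows = [], []
    for sample, group in config.design.items():
        grades = rng.choice(5, size=N_GLOMERULI, p=probs[group])
        row = {"animal": sample, "group": group}
        row.update({col: int(v) for col, v in zip(GRADE_COLUMNS, grades)})
        glom_rows.append(row)
        injury = float(np.clip(rng.normal(injury_mean[group], injury_sd), 0.0, 100.0))
        masson = float(
            np.clip(rng.normal(3.0 + 50.0 * cfg.dose_profile[group], 4.0), 0.0, 100.0)
        )
        tub_rows.append(
            {
                "animal": sample,
                "group": group,
                "injury_percent": round(injury, 3),
                "masson_percent": round(masson, 3),
            }
        )
    return HistologyTables(
        glomeruli=pd.DataFrame(glom_rows), tubulo=pd.DataFrame(tub_rows)
    )


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------


def simulate_ct_table(
    config: SimulationConfig,
    ct_effect_log2: float = 2.0,
    ct_noise_sd: float = 0.15,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ct values for a fibrosis marker panel plus the GAPDH reference.

    Marker genes gain ``-ct_effect_log2 * dose`` cycles (more template, lower
    Ct) with disease severity; anti-fibrotic genes the opposite; the
    reference gene is flat at 20 cycles.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    rows = []
    for sample, group in cfg.design.items():
        d = cfg.dose_profile[group]
        rows.append(
            {
                "sample": sample,
                "group": group,
                "gene": CT_REFERENCE_GENE,
                "ct": round(20.0 + rng.normal(0.0, ct_noise_sd), 4),
            }
        )
        for gene in CT_GENES_UP:
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": gene,
                    "ct": round(24.0 - ct_effect_log2 * d + rng.normal(0.0, ct_noise_sd), 4),
                }
            )
        for gene in CT_GENES_DOWN:
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": gene,
                    "ct": round(24.0 + ct_effect_log2 * d + rng.normal(0.0, ct_noise_sd), 4),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a simulated dataset to ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna_counts.tsv",
        "mirna": outdir / "mirna_counts.tsv",
        "lncrna": outdir / "lncrna_counts.tsv",
        "samples": outdir / "samples.tsv",
        "target_map": outdir / "target_map.tsv",
        "pathways": outdir / "pathways.gmt",
        "glomeruli": outdir / "histology_glomeruli.tsv",
        "tubulo": outdir / "histology_tubulo.tsv",
        "ct": outdir / "ct_table.tsv",
        "manifest": outdir / "ground_truth.json",
    }
    write_expression(dataset.mrna, paths["mrna"], paths["samples"])
    write_expression(dataset.mirna, paths["mirna"])
    write_expression(dataset.lncrna, paths["lncrna"])
    write_target_map(dataset.target_map, paths["target_map"])
    write_gmt(dataset.pathways, paths["pathways"])
    write_histology(dataset.histology, paths["glomeruli"], paths["tubulo"])
    write_ct_table(dataset.ct_table, paths["ct"])
    dataset.manifest.to_json(paths["manifest"])
    return paths
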