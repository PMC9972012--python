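"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators, all driven by one seed through named substreams:

* ``simulate_cohort`` — a microarray/RNA-seq-like log2-scale expression
  matrix for three planted subtypes. Background genes are Gaussian on the
  log2 scale; STING-signature genes shift +delta SD in STING-high and
  -delta in STING-low; NE-signature genes are drawn to correlate with a
  synthetic neuroendocrine reference profile in STING-low samples and
  with the non-NE profile in STING-high; immune marker sets are elevated
  in STING-high. Ground-truth labels are returned alongside.

* ``simulate_treatment_counts`` — negative-binomial count matrices for a
  control-vs-combination-treatment contrast with sample-specific library
  sizes and planted fold-change gene sets (an ISG-like up-set and an
  adhesion/neuronal-like down-set).

* ``simulate_variants`` — per-sample Bernoulli mutation indicators with
  subtype-specific rates per gene/pathway group, materialized as variant
  records, plus decoy records that each violate exactly one step of the
  somatic filter cascade (tagged with their ground-truth drop step).

Every gene identifier carries a SIM/SYNTHETIC marker: these signatures
are stand-ins with the right sizes (62/50/200/45/29 sets), not the real
published gene lists, which users supply via GMT when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LOG2P1, LINEAR, ExpressionMatrix, GeneSetCollection
from .scoring import NEReference
from .variants import VARIANT_COLUMNS

STING_SET = "STING_62_SYNTHETIC"
NE_SET = "NE_50_SYNTHETIC"
EMT_SET = "EMT_200_SYNTHETIC"
FERROPTOSIS_SET = "FERROPTOSIS_45_SYNTHETIC"

SUBTYPES = ("STING-high", "STING-intermediate", "STING-low")


def _default_mutation_rates() -> dict[str, dict[str, float]]:
    # NOTCH enriched in STING-low/intermediate; MMR mutations specific to
    # STING-high; TP53/RB1 near-ubiquitous and subtype-independent.
    return {
        "NOTCH": {"STING-high": 0.143, "STING-intermediate": 0.294, "STING-low": 0.304},
        "MMR": {"STING-high": 0.25, "STING-intermediate": 0.10, "STING-low": 0.0},
        "TP53": {"STING-high": 0.9, "STING-intermediate": 0.9, "STING-low": 0.9},
        "RB1": {"STING-high": 0.75, "STING-intermediate": 0.75, "STING-low": 0.75},
    }


PATHWAY_GENES = {
    "NOTCH": ["NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"],
    "MMR": ["MLH1", "MSH2", "MSH6", "PMS2"],
    "TP53": ["TP53"],
    "RB1": ["RB1"],
    "HRR": ["BRCA1", "BRCA2", "RAD51"],
    "NER": ["ERCC2", "ERCC3", "XPA"],
    "BER": ["OGG1", "XRCC1"],
    "NHEJ": ["PRKDC", "XRCC4"],
    "FA": ["FANCA", "FANCD2"],
    "TLS": ["POLH", "REV1"],
    "CPF": ["ATR", "CHEK1"],
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators (one seed, named streams)."""

    n_per_subtype: int = 20
    n_genes: int = 2000
    sting_size: int = 62
    ne_size: int = 50
    emt_size: int = 200
    ferroptosis_size: int = 45
    n_immune_sets: int = 29
    immune_set_size: int = 10
    delta: float = 2.0                 # STING-signature shift, in background-SD units
    ne_coupling: float = 0.9           # corr of STING-low samples with the NE reference
    immune_coupling: float = 1.0       # log2 elevation of immune markers in STING-high
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0
    # count simulation (control vs combined-treatment contrast)
    n_count_genes: int = 2000
    n_per_arm: int = 4
    fold_change: float = 4.0
    planted_set_size: int = 50
    nb_dispersion: float = 0.05
    library_range: tuple[float, float] = (0.7, 1.3)
    count_base_mean: float = 100.0
    # variant simulation
    mutation_rates: dict[str, dict[str, float]] = field(default_factory=_default_mutation_rates)
    n_decoys_per_step: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for tag, rates in self.mutation_rates.items():
            for lab, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"mutation rate {tag}/{lab}={r} outside [0,1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not -1.0 <= self.ne_coupling <= 1.0:
            raise ValueError("ne_coupling must be a correlation in [-1, 1]")
        for size in (self.n_per_subtype, self.n_genes, self.sting_size, self.ne_size):
            if size <= 0:
                raise ValueError("sizes must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    sting = [f"STINGSIM{i:03d}" for i in range(1, cfg.sting_size + 1)]
    ne = [f"NESIM{i:03d}" for i in range(1, cfg.ne_size + 1)]
    emt = [f"EMTSIM{i:03d}" for i in range(1, cfg.emt_size + 1)]
    ferr = [f"FERRSIM{i:03d}" for i in range(1, cfg.ferroptosis_size + 1)]
    immune = {
        f"IMMUNE_SIM_{s:02d}": [f"IMMSIM{s:02d}G{j:02d}" for j in range(1, cfg.immune_set_size + 1)]
        for s in range(1, cfg.n_immune_sets + 1)
    }
    sets = {STING_SET: sting, NE_SET: ne, EMT_SET: emt, FERROPTOSIS_SET: ferr, **immune}
    n_sig = sum(len(v) for v in sets.values())
    if cfg.n_genes < n_sig + 10:
        raise ValueError(f"n_genes={cfg.n_genes} too small for {n_sig} signature genes")
    background = [f"BGSIM{i:05d}" for i in range(1, cfg.n_genes - n_sig + 1)]
    genes = [g for gl in sets.values() for g in gl] + background
    return genes, sets


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, GeneSetCollection, NEReference]:
    """Simulate a log2-scale three-subtype cohort; returns truth labels too."""
    rng = cfg.rng(1)
    genes, sets = _gene_names(cfg)
    n_samples = 3 * cfg.n_per_subtype
    sample_ids = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    labels = pd.Series(
        [lab for lab in SUBTYPES for _ in range(cfg.n_per_subtype)],
        index=sample_ids, name="subtype",
    )

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n_samples))
    df = pd.DataFrame(X, index=genes, columns=sample_ids)

    is_high = (labels == "STING-high").to_numpy()
    is_low = (labels == "STING-low").to_numpy()

    # STING signature: +delta SD in high, -delta in low, with per-gene effect
    # weights (mean 1) — pathway activation moves member genes by unequal
    # amounts, and that heterogeneity is what sample-correlation clustering sees
    weights = rng.gamma(shape=4.0, scale=0.25, size=cfg.sting_size)
    shift = cfg.delta * cfg.noise_sd * weights
    df.loc[sets[STING_SET], labels.index[is_high]] += shift[:, None]
    df.loc[sets[STING_SET], labels.index[is_low]] -= shift[:, None]

    # NE reference: two independent synthetic mean profiles over the NE genes
    ne_profile = rng.normal(cfg.baseline_mean, 2.0, size=cfg.ne_size)
    nonne_profile = rng.normal(cfg.baseline_mean, 2.0, size=cfg.ne_size)
    ref = NEReference(list(sets[NE_SET]), ne_profile, nonne_profile)
    z_ne = (ne_profile - ne_profile.mean()) / ne_profile.std()
    z_nonne = (nonne_profile - nonne_profile.mean()) / nonne_profile.std()
    c = cfg.ne_coupling
    resid = np.sqrt(max(0.0, 1.0 - c * c))
    for j, sid in enumerate(sample_ids):
        eps = rng.normal(0.0, 1.0, size=cfg.ne_size)
        if is_low[j]:
            v = c * z_ne + resid * eps
        elif is_high[j]:
            v = c * z_nonne + resid * eps
        else:
            mix = (z_ne + z_nonne) / np.sqrt(2.0)
            v = c * mix / np.std(mix) + resid * eps
        df.loc[sets[NE_SET], sid] = cfg.baseline_mean + 1.5 * v

    # immune marker sets elevated in STING-high
    immune_genes = [g for name, gl in sets.items() if name.startswith("IMMUNE_SIM_") for g in gl]
    df.loc[immune_genes, labels.index[is_high]] += cfg.immune_coupling
    # EMT up / ferroptosis up in high as in the reported phenotype, milder
    df.loc[sets[EMT_SET], labels.index[is_high]] += 0.5 * cfg.immune_coupling
    df.loc[sets[FERROPTOSIS_SET], labels.index[is_low]] -= 0.5 * cfg.immune_coupling

    df = df.clip(lower=0.0)  # log2(x+1) values are non-negative
    meta = pd.DataFrame({"cohort": "synthetic", "subtype_truth": labels}, index=sample_ids)
    gs = GeneSetCollection(
        sets,
        {name: "synthetic stand-in signature (not the published gene list)" for name in sets},
    )
    return ExpressionMatrix(df, LOG2P1, meta), labels, gs, ref


def simulate_treatment_counts(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, set[str], set[str]]:
    """Negative-binomial pre/post count matrices with planted DE gene sets."""
    if cfg.fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = cfg.rng(2)
    up = [f"ISGSIM{i:03d}" for i in range(1, cfg.planted_set_size + 1)]
    down = [f"ADHSIM{i:03d}" for i in range(1, cfg.planted_set_size + 1)]
    n_bg = cfg.n_count_genes - 2 * cfg.planted_set_size
    genes = up + down + [f"CBG{i:05d}" for i in range(1, n_bg + 1)]

    base = rng.lognormal(mean=np.log(cfg.count_base_mean), sigma=1.0, size=len(genes))
    lo, hi = cfg.library_range
    lib_pre = rng.uniform(lo, hi, size=cfg.n_per_arm)
    lib_post = rng.uniform(lo, hi, size=cfg.n_per_arm)

    fc = np.ones(len(genes))
    fc[: cfg.planted_set_size] = cfg.fold_change
    fc[cfg.planted_set_size: 2 * cfg.planted_set_size] = 1.0 / cfg.fold_change

    def draw(mu: np.ndarray) -> np.ndarray:
        # gamma-Poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu * cfg.nb_dispersion)
        return rng.poisson(lam).astype(float)

    pre = np.column_stack([draw(base * l) for l in lib_pre])
    post = np.column_stack([draw(base * fc * l) for l in lib_post])
    pre_ids = [f"CTRL_{i}" for i in range(1, cfg.n_per_arm + 1)]
    post_ids = [f"TREAT_{i}" for i in range(1, cfg.n_per_arm + 1)]
    m_pre = ExpressionMatrix(pd.DataFrame(pre, index=genes, columns=pre_ids), LINEAR)
    m_post = ExpressionMatrix(pd.DataFrame(post, index=genes, columns=post_ids), LINEAR)
    return m_pre, m_post, set(up), set(down)


def simulate_variants(cfg: SimulationConfig, labels: pd.Series) -> pd.DataFrame:
    """Subtype-dependent mutation events plus per-filter-step decoy records.

    Real somatic events pass the whole filter cascade (VAF in [0.1, 0.6],
    exonic, absent from population db and matched normal); each decoy
    violates exactly one step and records it in ``truth_drop_step``.
    """
    rng = cfg.rng(3)
    rows: list[dict] = []
    sample_ids = list(labels.index)
    for sid in sample_ids:
        lab = labels[sid]
        for tag, rates in cfg.mutation_rates.items():
            rate = rates.get(lab, 0.0)
            if rng.random() < rate:
                gene = str(rng.choice(PATHWAY_GENES.get(tag, [f"{tag}GENE"])))
                rows.append({
                    "sample_id": sid, "gene": gene, "chrom": str(rng.integers(1, 23)),
                    "position": int(rng.integers(1, 10_000_000)),
                    "ref": "A", "alt": "T",
                    "vaf": float(rng.uniform(0.1, 0.6)),
                    "region_class": "exonic", "in_1000g": False,
                    "in_matched_normal": False, "pathway_tags": tag,
                    "truth_drop_step": "",
                })

    def decoy(step: str) -> dict:
        d = {
            "sample_id": str(rng.choice(sample_ids)), "gene": "DECOYSIM",
            "chrom": str(rng.integers(1, 23)), "position": int(rng.integers(1, 10_000_000)),
            "ref": "C", "alt": "G", "vaf": float(rng.uniform(0.1, 0.6)),
            "region_class": "exonic", "in_1000g": False, "in_matched_normal": False,
            "pathway_tags": "", "truth_drop_step": step,
        }
        if step == "low_vaf":
            d["vaf"] = float(rng.uniform(0.01, 0.0999))
        elif step == "intronic_utr":
            d["region_class"] = str(rng.choice(["intronic", "UTR3", "UTR5"]))
        elif step == "thousand_genomes":
            d["in_1000g"] = True
        elif step == "matched_normal":
            d["in_matched_normal"] = True
        return d

    for step in ("low_vaf", "intronic_utr", "thousand_genomes", "matched_normal"):
        rows.extend(decoy(step) for _ in range(cfg.n_decoys_per_step))

    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS + ["truth_drop_step"])
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["truth_drop_step"])
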