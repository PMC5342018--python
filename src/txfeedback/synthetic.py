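"""Synthetic study generator with planted ground truth.

Emulates a keratinocyte inhibitor-response design: four genetic backgrounds
(Mock, EGFR-overexpressing, HRAS-mutant, PIK3CA-mutant) crossed with four
treatments (vehicle control plus three EGFR inhibitors), measured in
triplicate on a two-probe-per-gene array.  Three expression programs are
planted:

1. a constant program (baseline expression, identical in every condition);
2. an oncogene-driven program, highest in the HRAS-mutant background and
   repressed by treatment in proportion to each background's drug
   sensitivity;
3. a feedback program, lowest in the HRAS-mutant background and induced by
   treatment in sensitive backgrounds.

TF target sets are planted on programs 2 and 3.  The "AP2A" set contains a
reference gene (playing the role of EGFR) and splits into "up" members
(feedback-induced, program 3) and "down" members (treatment-repressed,
program 2).  A colony-survival phenotype is planted as a negative affine
function of the feedback program's treatment delta, so survival is
anti-correlated with feedback induction by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .preprocess import ExpressionBundle, condition_label

PATTERN_NAMES = ("constant", "oncogenic", "feedback")

# Fraction of each background's feedback induction (program 3, in units of
# the untreated level) realized under a unit-potency drug.
_DEFAULT_SENSITIVITY = {"Mock": 1.0, "EGFR": 0.9, "PIK3CA": 0.5, "HRAS": 0.05}
# Program 2 is repressed in every background, deepest where the driving
# pathway is most active (the resistant, oncogene-driven line), so its
# treatment delta tracks relative survival rather than sensitivity.
_REPRESSION_DEPTH_MIN = 0.3
_REPRESSION_DEPTH_SPAN = 0.35
_INDUCTION_GAIN = 2.0
_SURVIVAL_SLOPE = 9.0
_SURVIVAL_NOISE_SD = 0.015


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    ``pattern_effect_sizes`` are the amplitude scales of the three planted
    programs in A (log2-intensity units before pattern normalization):
    the constant baseline, the oncogene-driven program, and the feedback
    program.
    """

    n_genes: int = 500
    n_tf: int = 3
    targets_per_tf: int = 40
    backgrounds: tuple[str, ...] = ("Mock", "EGFR", "HRAS", "PIK3CA")
    treatments: tuple[str, ...] = ("control", "cetuximab", "gefitinib", "afatinib")
    n_replicates: int = 3
    probes_per_gene: int = 2
    noise_sd: float = 0.3
    pattern_effect_sizes: tuple[float, float, float] = (112.0, 20.0, 26.0)
    up_fraction: float = 0.6
    anchor_fraction: float = 0.3
    anchor_scale: float = 0.15
    resistant_background: str = "HRAS"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_genes": self.n_genes, "n_tf": self.n_tf,
                  "targets_per_tf": self.targets_per_tf,
                  "n_replicates": self.n_replicates,
                  "probes_per_gene": self.probes_per_gene}
        for name, val in counts.items():
            if val < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {val}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for labels, what in ((self.backgrounds, "backgrounds"), (self.treatments, "treatments")):
            if len(set(labels)) != len(labels):
                raise ConfigurationError(f"{what} labels must be unique")
        if len(self.treatments) < 2:
            raise ConfigurationError("need a control plus at least one treatment")
        if self.n_tf * self.targets_per_tf > self.n_genes:
            raise ConfigurationError("more TF targets than genes")
        if not 0 < self.up_fraction < 1:
            raise ConfigurationError("up_fraction must lie in (0, 1)")
        if not 0 <= self.anchor_fraction <= 1:
            raise ConfigurationError("anchor_fraction must lie in [0, 1]")
        if not 0 < self.anchor_scale <= 1:
            raise ConfigurationError("anchor_scale must lie in (0, 1]")

    @property
    def conditions(self) -> list[str]:
        return [condition_label(b, t) for b in self.backgrounds for t in self.treatments]

    @property
    def control(self) -> str:
        return self.treatments[0]

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.treatments[1:]

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def tf_names(self) -> list[str]:
        stock = ["Elk1", "AP2A", "SP1"]
        extra = [f"TF{i + 1}" for i in range(max(0, self.n_tf - len(stock)))]
        return (stock + extra)[: self.n_tf]


@dataclass
class GroundTruth:
    """Planted factors, target sets, signature memberships and survival."""

    A_true: pd.DataFrame            # genes x 3 patterns, nonnegative
    P_true: pd.DataFrame            # 3 patterns x conditions, rows sum to 1
    tf_targets: dict[str, set[str]]
    signature_truth: dict           # {"reference": str, "up": set, "down": set}
    survival_true: pd.Series        # (background, drug) -> fraction in (0, 1]

    def __post_init__(self) -> None:
        if (self.A_true.to_numpy() < 0).any() or (self.P_true.to_numpy() < 0).any():
            raise ConfigurationError("planted factors must be nonnegative")
        sums = self.P_true.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigurationError("P_true rows must sum to 1")
        if self.signature_truth["up"] & self.signature_truth["down"]:
            raise ConfigurationError("up and down signature sets must be disjoint")


def _sensitivity(config: SimConfig) -> dict[str, float]:
    sens = {}
    for bg in config.backgrounds:
        if bg == config.resistant_background:
            sens[bg] = _DEFAULT_SENSITIVITY.get(bg, 0.05)
        else:
            sens[bg] = _DEFAULT_SENSITIVITY.get(bg, 0.7)
    return sens


def _drug_potency(config: SimConfig) -> dict[str, float]:
    drugs = config.drugs
    if len(drugs) == 1:
        return {drugs[0]: 1.0}
    return {d: p for d, p in zip(drugs, np.linspace(0.9, 1.1, len(drugs)))}


def generate_truth(config: SimConfig) -> GroundTruth:
    """Construct the planted factors, target sets and survival phenotype."""
    rng = np.random.default_rng([config.seed, 0])
    sens = _sensitivity(config)
    potency = _drug_potency(config)
    resistant = config.resistant_background

    raw = np.zeros((3, len(config.conditions)))
    for j, cond in enumerate(config.conditions):
        bg, tr = cond.split("|", 1)
        base2 = 3.0 if bg == resistant else 1.0
        base3 = 0.5 if bg == resistant else 1.0
        raw[0, j] = 1.0
        if tr == config.control:
            raw[1, j] = base2
            raw[2, j] = base3
        else:
            depth = _REPRESSION_DEPTH_MIN + _REPRESSION_DEPTH_SPAN * (1.0 - sens[bg])
            raw[1, j] = base2 * (1.0 - depth * potency[tr])
            raw[2, j] = base3 + _INDUCTION_GAIN * sens[bg] * potency[tr]
    P_true = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True),
                          index=list(PATTERN_NAMES), columns=config.conditions)

    genes = config.gene_ids()
    tf_names = config.tf_names()
    picked = rng.choice(len(genes), size=config.n_tf * config.targets_per_tf, replace=False)
    tf_targets: dict[str, set[str]] = {}
    blocks: dict[str, list[str]] = {}
    for i, tf in enumerate(tf_names):
        block = [genes[g] for g in picked[i * config.targets_per_tf:(i + 1) * config.targets_per_tf]]
        blocks[tf] = block
        tf_targets[tf] = set(block)

    elk_block = blocks.get("Elk1", blocks[tf_names[0]])
    ap2_block = blocks.get("AP2A", blocks[tf_names[min(1, len(tf_names) - 1)]])
    n_up = max(1, int(round(config.up_fraction * len(ap2_block))))
    up_list = ap2_block[:n_up]
    down_list = ap2_block[n_up:]
    up, down = set(up_list), set(down_list)
    reference = ap2_block[0]
    if "SP1" in tf_targets:  # decoy annotation: reference gene also claimed by SP1
        tf_targets["SP1"].add(reference)

    s1, s2, s3 = config.pattern_effect_sizes
    A = np.zeros((len(genes), 3))
    A[:, 0] = rng.uniform(0.8, 1.2, len(genes)) * s1
    idx = {g: i for i, g in enumerate(genes)}
    for g in elk_block:
        A[idx[g], 1] = rng.uniform(0.67, 1.33) * s2
    for g in down_list:
        A[idx[g], 1] = rng.uniform(0.67, 1.33) * s2
    for g in up_list:
        A[idx[g], 2] = rng.uniform(0.67, 1.33) * s3
    # A fraction of each program's genes are strongly inducible, with low
    # constitutive expression: their measurement is dominated by the program
    # itself.  Such genes anchor the factorization (separability).
    for block in (elk_block, up_list, down_list):
        n_anchor = max(1, int(round(config.anchor_fraction * len(block)))) \
            if config.anchor_fraction > 0 and block else 0
        for g in block[:n_anchor]:
            A[idx[g], 0] *= config.anchor_scale
    A_true = pd.DataFrame(A, index=genes, columns=list(PATTERN_NAMES))

    deltas, keys = [], []
    for bg in config.backgrounds:
        for drug in config.drugs:
            delta = (P_true.loc["feedback", condition_label(bg, drug)]
                     - P_true.loc["feedback", condition_label(bg, config.control)])
            deltas.append(delta)
            keys.append((bg, drug))
    noise = rng.normal(0.0, _SURVIVAL_NOISE_SD, len(deltas))
    surv = np.clip(1.0 - _SURVIVAL_SLOPE * np.asarray(deltas) + noise, 0.01, 1.0)
    survival_true = pd.Series(surv, index=pd.MultiIndex.from_tuples(keys, names=["background", "treatment"]),
                              name="relative_survival")

    return GroundTruth(A_true=A_true, P_true=P_true, tf_targets=tf_targets,
                       signature_truth={"reference": reference, "up": up, "down": down},
                       survival_true=survival_true)


def simulate_expression(truth: GroundTruth, config: SimConfig) -> ExpressionBundle:
    """Probe-level noisy measurements of the planted expression surface.

    Each gene gets ``probes_per_gene`` probes; exactly one (chosen at random
    per gene) tracks the planted signal ``(A_true @ P_true)`` while the rest
    sit at a flat, condition-independent level.  All probes receive i.i.d.
    Gaussian noise per replicate on the log2 scale.
    """
    genes = config.gene_ids()
    if list(truth.A_true.index) != genes or list(truth.P_true.columns) != config.conditions:
        raise InputError("ground truth dimensions do not match the configuration")
    rng = np.random.default_rng([config.seed, 1])

    expected = truth.A_true.to_numpy() @ truth.P_true.to_numpy()  # genes x conditions
    informative = rng.integers(0, config.probes_per_gene, len(genes))
    flat_levels = rng.uniform(4.0, 8.0, (len(genes), config.probes_per_gene))

    n_cond = len(config.conditions)
    n_samples = n_cond * config.n_replicates
    sample_ids, meta_rows = [], []
    for bg in config.backgrounds:
        for tr in config.treatments:
            for r in range(1, config.n_replicates + 1):
                sample_ids.append(f"{bg}.{tr}.r{r}")
                meta_rows.append({"sample_id": f"{bg}.{tr}.r{r}", "background": bg,
                                  "treatment": tr, "replicate": r})
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # Per-sample expected value for every probe.
    cond_index = np.repeat(np.arange(n_cond), config.n_replicates)
    probe_ids, probe_genes = [], []
    signal = np.empty((len(genes) * config.probes_per_gene, n_samples))
    row = 0
    for gi, gene in enumerate(genes):
        for p in range(config.probes_per_gene):
            probe_ids.append(f"{gene}_p{p + 1}")
            probe_genes.append(gene)
            if p == informative[gi]:
                signal[row] = expected[gi, cond_index]
            else:
                signal[row] = flat_levels[gi, p]
            row += 1
    values = signal + rng.normal(0.0, config.noise_sd, signal.shape)
    bundle = ExpressionBundle(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        sample_meta=sample_meta,
        probe_map=pd.Series(probe_genes, index=probe_ids, name="gene"),
    )
    return bundle


def informative_probes(truth: GroundTruth, config: SimConfig) -> pd.Series:
    """Gene -> planted informative probe id (regenerated from the seed)."""
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_ids()
    informative = rng.integers(0, config.probes_per_gene, len(genes))
    return pd.Series([f"{g}_p{p + 1}" for g, p in zip(genes, informative)],
                     index=genes, name="probe")


def signal_genes(truth: GroundTruth) -> list[str]:
    """Genes carrying condition-dependent planted signal (programs 2 or 3)."""
    loaded = truth.A_true[["oncogenic", "feedback"]].sum(axis=1) > 0
    return truth.A_true.index[loaded].tolist()


def simulate_alterations(n_samples: int, event_rates: dict, seed: int,
                         tumor_type: str = "SYNTH") -> pd.DataFrame:
    """Per-sample mutation flags and GISTIC scores with stated marginal rates.

    ``event_rates`` maps gene -> mutation probability (float), or gene ->
    ``{"mutation": p, "amplification": p, "deletion": p}``.  Amplification and
    deletion produce GISTIC +2 / -2 (mutually exclusive); remaining samples
    get shallow scores (-1, 0, +1) that never count as alterations.

    Returns a long-format table with columns ``sample_id``, ``tumor_type``,
    ``gene``, ``mutated``, ``gistic``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sample_ids = [f"{tumor_type}.s{i + 1:04d}" for i in range(n_samples)]
    for gene, spec_rates in event_rates.items():
        if isinstance(spec_rates, dict):
            p_mut = spec_rates.get("mutation", 0.0)
            p_amp = spec_rates.get("amplification", 0.0)
            p_del = spec_rates.get("deletion", 0.0)
        else:
            p_mut, p_amp, p_del = float(spec_rates), 0.0, 0.0
        for name, p in (("mutation", p_mut), ("amplification", p_amp), ("deletion", p_del)):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} rate for {gene} outside [0, 1]: {p}")
        if p_amp + p_del > 1.0:
            raise InputError(f"amplification + deletion rates exceed 1 for {gene}")
        mutated = rng.random(n_samples) < p_mut
        u = rng.random(n_samples)
        gistic = np.zeros(n_samples, dtype=int)
        gistic[u < p_amp] = 2
        gistic[(u >= p_amp) & (u < p_amp + p_del)] = -2
        shallow = gistic == 0
        v = rng.random(n_samples)
        gistic[shallow & (v < 0.1)] = -1
        gistic[shallow & (v >= 0.9)] = 1
        for i in range(n_samples):
            rows.append({"sample_id": sample_ids[i], "tumor_type": tumor_type,
                         "gene": gene, "mutated": bool(mutated[i]),
                         "gistic": int(gistic[i])})
    return pd.DataFrame(rows, columns=["sample_id", "tumor_type", "gene", "mutated", "gistic"])


def relative_survival(treated_area: float, control_area: float) -> float:
    """Colony-formation survival: treated total colony area as % of control."""
    if control_area <= 0:
        raise InputError(f"control_area must be > 0, got {control_area}")
    if treated_area < 0:
        raise InputError(f"treated_area must be >= 0, got {treated_area}")
    return 100.0 * treated_area / control_area
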