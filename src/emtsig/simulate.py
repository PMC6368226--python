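"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study designs the pipeline consumes, so
derivation, translation, scoring, survival and association analyses can
all be exercised and verified offline against known truth:

* a multi-cell-line TGFβ time course with responder, non-responder and
  constitutively mesenchymal lines, and planted EMT-up/EMT-down,
  no-EMT, shared-TGFβ-response and null probesets;
* tumor cohorts in which signature-gene expression tracks a latent EMT
  activity z that also raises the metastasis and death hazards
  (two exponential clocks sharing γ·z in their log-hazards, the
  metastasis clock on an earlier scale — matching a composite
  metastasis-or-death endpoint without further biological assumptions);
* a colon-style cohort with a baseline metastasis-at-surgery label whose
  carriers are drawn from a shifted latent-activity distribution;
* binary mutation tables with carrier probabilities that depend on the
  sign of z for planted-enriched genes.

All generators are pure functions of (config, seed).  Defaults mirror
the cell-line experiment's scale (4 responder + 8 non-responder lines,
two treated time points plus untreated controls, 1.5 log2-unit effects
over 0.3-sd noise); everything is overridable through the config
dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .signature import Signature


@dataclass
class CellLineDesign:
    """Layout of the simulated TGFβ time-course experiment."""

    n_responder: int = 4
    n_nonresponder: int = 8
    n_mesenchymal: int = 1
    treated_times: tuple = (24.0, 120.0)
    n_control_replicates: int = 2

    def validate(self) -> None:
        if self.n_responder < 1 or self.n_nonresponder < 1:
            raise ValueError("need at least one responder and one non-responder line")
        if self.n_mesenchymal < 0 or self.n_control_replicates < 1:
            raise ValueError("invalid cell-line design counts")
        if not self.treated_times:
            raise ValueError("need at least one treated time point")


@dataclass
class ProbesetDesign:
    """Planted probeset classes, effect size and noise of the time course."""

    n_emt_up: int = 30
    n_emt_down: int = 30
    n_no_emt: int = 20
    n_shared_tgfb: int = 20
    n_null: int = 400
    effect_log2: float = 1.5
    noise_sd: float = 0.3
    baseline_sd: float = 1.0
    baseline_mean: float = 8.0

    def validate(self) -> None:
        if min(self.n_emt_up, self.n_emt_down, self.n_no_emt,
               self.n_shared_tgfb, self.n_null) < 0:
            raise ValueError("probeset counts must be non-negative")
        if self.n_emt_up + self.n_emt_down == 0:
            raise ValueError("need at least one planted EMT probeset")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise and baseline sds must be positive")
        if self.effect_log2 < 0:
            raise ValueError("effect size must be non-negative")


@dataclass
class CohortDesign:
    """Latent-activity tumor cohort: expression, hazards, censoring."""

    n_patients: int = 150
    beta: float = 1.0                    # latent-activity loading on signature genes
    noise_sd: float = 0.5
    n_null_probesets: int = 100
    gamma: float = 0.7                   # log-hazard coefficient of z
    baseline_hazard_death: float = 1.0 / 80.0   # per month
    baseline_hazard_met: float = 1.0 / 40.0     # earlier-scale metastasis clock
    followup_max: float = 120.0          # months; uniform censoring horizon
    baseline_metastasis_prob: float = 0.02
    stage_probs: dict = field(default_factory=lambda: {
        "IA": 0.38, "IB": 0.17, "II": 0.16, "III": 0.20, "IV": 0.09})

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if self.noise_sd <= 0 or self.followup_max <= 0:
            raise ValueError("noise sd and follow-up horizon must be positive")
        if min(self.baseline_hazard_death, self.baseline_hazard_met) <= 0:
            raise ValueError("baseline hazards must be positive")
        if not 0 <= self.baseline_metastasis_prob <= 1:
            raise ValueError("baseline_metastasis_prob must be in [0, 1]")
        if abs(sum(self.stage_probs.values()) - 1) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")


@dataclass
class ColonDesign:
    """Baseline-metastasis colon-style cohort."""

    n_patients: int = 96
    met_prevalence: float = 0.25
    shift: float = 1.0                   # latent-activity shift of carriers, in sd
    beta: float = 1.0
    noise_sd: float = 0.5
    n_null_probesets: int = 100

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if not 0 <= self.met_prevalence <= 1:
            raise ValueError("met_prevalence must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


@dataclass
class MutationDesign:
    """Per-gene carrier probabilities on the two sides of the latent axis.

    ``genes`` maps gene symbol → (carrier probability when z > 0,
    carrier probability when z ≤ 0); unequal probabilities plant an
    enrichment.  Defaults plant low-score enrichment for KEAP1-like and
    HGF-like genes, high-score enrichment for a ZNF831-like gene, and
    several null genes.
    """

    genes: dict = field(default_factory=lambda: {
        "KEAP1": (0.05, 0.4), "HGF": (0.05, 0.4), "ZNF831": (0.4, 0.05),
        "NULL1": (0.2, 0.2), "NULL2": (0.2, 0.2), "NULL3": (0.1, 0.1)})

    def validate(self) -> None:
        for g, (p_hi, p_lo) in self.genes.items():
            if not (0 <= p_hi <= 1 and 0 <= p_lo <= 1):
                raise ValueError(f"carrier probabilities for {g} must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Bundle of all generator designs; each is independently overridable."""

    cellline: CellLineDesign = field(default_factory=CellLineDesign)
    probesets: ProbesetDesign = field(default_factory=ProbesetDesign)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    colon: ColonDesign = field(default_factory=ColonDesign)
    mutations: MutationDesign = field(default_factory=MutationDesign)

    def validate(self) -> None:
        self.cellline.validate()
        self.probesets.validate()
        self.cohort.validate()
        self.colon.validate()
        self.mutations.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _probeset_truth(pd_design: ProbesetDesign) -> pd.DataFrame:
    rows = []
    for i in range(pd_design.n_emt_up):
        rows.append((f"EMTUP{i + 1:04d}", "emt", 1))
    for i in range(pd_design.n_emt_down):
        rows.append((f"EMTDN{i + 1:04d}", "emt", -1))
    for i in range(pd_design.n_no_emt):
        rows.append((f"NOEMT{i + 1:04d}", "no_emt", 1 if i % 2 == 0 else -1))
    for i in range(pd_design.n_shared_tgfb):
        rows.append((f"SHARE{i + 1:04d}", "shared_tgfb", 1 if i % 2 == 0 else -1))
    for i in range(pd_design.n_null):
        rows.append((f"NULL{i + 1:05d}", "null", 0))
    return pd.DataFrame(rows, columns=["probeset_id", "true_class", "direction"])


def simulate_cellline_experiment(cfg: SimulationConfig, seed: int):
    """Simulate the multi-line TGFβ time course.

    Returns ``(ExpressionMatrix, annotation, truth)``.  Expression is
    per-probeset baseline + per-line offset + treatment effect + noise.
    EMT probesets respond (direction × effect) only in treated responder
    lines; no-EMT probesets only in treated non-responder lines; shared
    probesets in all treated lines.  Constitutively mesenchymal lines
    carry the mesenchymal (EMT-shifted) expression untreated and
    treated.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    des, pdes = cfg.cellline, cfg.probesets
    truth = _probeset_truth(pdes)
    probesets = truth["probeset_id"].to_numpy()
    n_p = len(probesets)
    classes = truth["true_class"].to_numpy()
    dirs = truth["direction"].to_numpy().astype(float)

    lines = ([(f"RESP{i + 1:02d}", "EMT-responder") for i in range(des.n_responder)]
             + [(f"NONR{i + 1:02d}", "non-EMT") for i in range(des.n_nonresponder)]
             + [(f"MESN{i + 1:02d}", "constitutively-mesenchymal")
                for i in range(des.n_mesenchymal)])

    baseline = rng.normal(pdes.baseline_mean, 1.5, size=n_p)
    ann_rows = []
    cols = {}
    for line, phen in lines:
        line_offset = rng.normal(0.0, pdes.baseline_sd, size=n_p)
        base = baseline + line_offset
        mes_shift = np.where(classes == "emt", dirs * pdes.effect_log2, 0.0) \
            if phen == "constitutively-mesenchymal" else 0.0
        for r in range(des.n_control_replicates):
            sid = f"{line}_U0_r{r + 1}"
            cols[sid] = base + mes_shift + rng.normal(0, pdes.noise_sd, n_p)
            ann_rows.append((sid, line, "untreated", 0.0, phen))
        for t in des.treated_times:
            effect = np.zeros(n_p)
            if phen == "EMT-responder":
                effect += np.where(classes == "emt", dirs * pdes.effect_log2, 0.0)
            if phen == "non-EMT":
                effect += np.where(classes == "no_emt", dirs * pdes.effect_log2, 0.0)
            effect += np.where(classes == "shared_tgfb", dirs * pdes.effect_log2, 0.0)
            sid = f"{line}_T{int(t)}"
            cols[sid] = (base + np.asarray(mes_shift) + effect
                         + rng.normal(0, pdes.noise_sd, n_p))
            ann_rows.append((sid, line, "treated", float(t), phen))

    values = pd.DataFrame(cols, index=probesets)
    symbols = pd.Series([f"G{p}" for p in probesets], index=probesets)
    ann = pd.DataFrame(ann_rows, columns=["sample_id", "unit_id", "treatment",
                                          "time_hours", "phenotype_class"])
    return ExpressionMatrix(values, symbols), ann, truth


def _cohort_expression(rng, sig: Signature, z: np.ndarray, beta: float,
                       noise_sd: float, n_null: int,
                       discordant: set | None = None) -> ExpressionMatrix:
    n = len(z)
    sample_ids = [f"PT{i + 1:04d}" for i in range(n)]
    dirs = sig.directions
    sym_map = sig.entries.set_index("probeset_id")["gene_symbol"]
    rows = {}
    symbols = {}
    for p in sig.probeset_ids:
        d = float(dirs[p])
        if discordant and p in discordant:
            d = -d
        rows[p] = d * beta * z + rng.normal(0, noise_sd, n)
        symbols[p] = sym_map.get(p, "")
    for i in range(n_null):
        p = f"CNULL{i + 1:04d}"
        rows[p] = rng.normal(0, 1.0, n)
        symbols[p] = f"G{p}"
    values = pd.DataFrame(rows, index=sample_ids).T
    return ExpressionMatrix(values, pd.Series(symbols))


def simulate_tumor_cohort(cfg: SimulationConfig, sig: Signature, seed: int,
                          discordant_probesets: list | None = None):
    """Simulate a tumor cohort with latent-activity-driven outcomes.

    Latent EMT activity z ~ N(0, 1) drives signature-gene expression
    (direction × β × z + noise; ``discordant_probesets`` get the flipped
    sign) and both event clocks: metastasis and death times are
    exponential with hazards h₀ · exp(γ·z).  Censoring is uniform on
    (0, follow-up horizon), independent of z.  Returns
    ``(ExpressionMatrix, annotation, truth)``; the annotation carries
    os/met times and events, the baseline-metastasis flag and a stage
    label, the truth table z and the true hazards.
    """
    cfg.validate()
    if len(sig) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng(seed)
    des = cfg.cohort
    z = rng.standard_normal(des.n_patients)
    m = _cohort_expression(rng, sig, z, des.beta, des.noise_sd,
                           des.n_null_probesets,
                           set(discordant_probesets or []))
    h_death = des.baseline_hazard_death * np.exp(des.gamma * z)
    h_met = des.baseline_hazard_met * np.exp(des.gamma * z)
    t_death = rng.exponential(1.0 / h_death)
    t_met = rng.exponential(1.0 / h_met)
    censor = rng.uniform(0, des.followup_max, des.n_patients)
    os_time = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    met_time = np.minimum(t_met, censor)
    met_event = (t_met <= censor).astype(int)
    stages = rng.choice(list(des.stage_probs), size=des.n_patients,
                        p=list(des.stage_probs.values()))
    baseline_met = rng.random(des.n_patients) < des.baseline_metastasis_prob
    ann = pd.DataFrame({
        "sample_id": m.sample_ids,
        "os_time": os_time, "os_event": os_event,
        "met_time": met_time, "met_event": met_event,
        "baseline_metastasis": baseline_met,
        "stage": stages,
    })
    truth = pd.DataFrame({"sample_id": m.sample_ids, "z": z,
                          "hazard_death": h_death, "hazard_met": h_met})
    return m, ann, truth


def simulate_colon_cohort(cfg: SimulationConfig, sig: Signature, seed: int):
    """Simulate a colon-style cohort with a metastasis-at-surgery label.

    Carriers of the label have latent activity shifted by ``shift`` sd,
    so their signature scores are systematically higher.  Returns
    ``(ExpressionMatrix, annotation)`` with a ``met_at_surgery`` column.
    """
    cfg.validate()
    if len(sig) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng(seed)
    des = cfg.colon
    label = rng.random(des.n_patients) < des.met_prevalence
    z = rng.standard_normal(des.n_patients) + des.shift * label
    m = _cohort_expression(rng, sig, z, des.beta, des.noise_sd,
                           des.n_null_probesets)
    ann = pd.DataFrame({"sample_id": m.sample_ids,
                        "met_at_surgery": label.astype(int),
                        "z": z})
    return m, ann


def simulate_mutation_cohort(cfg: SimulationConfig, sig: Signature, seed: int):
    """Simulate a cohort with expression plus binary mutation columns.

    Expression follows the tumor-cohort model.  For each configured gene,
    carrier probability is the first configured value where z > 0 (the
    eventual high-score side) and the second where z ≤ 0; unequal values
    plant a cluster enrichment.  Returns ``(ExpressionMatrix,
    annotation with mut_<GENE> columns, truth)``.
    """
    cfg.validate()
    if len(sig) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng(seed)
    des = cfg.cohort
    z = rng.standard_normal(des.n_patients)
    m = _cohort_expression(rng, sig, z, des.beta, des.noise_sd,
                           des.n_null_probesets)
    ann = pd.DataFrame({"sample_id": m.sample_ids})
    truth_rows = []
    for gene, (p_hi, p_lo) in cfg.mutations.genes.items():
        prob = np.where(z > 0, p_hi, p_lo)
        ann[f"mut_{gene}"] = (rng.random(des.n_patients) < prob).astype(int)
        truth_rows.append((gene, p_hi, p_lo, p_hi != p_lo))
    truth = pd.DataFrame(truth_rows,
                         columns=["gene", "p_high_side", "p_low_side", "enriched"])
    truth_z = pd.DataFrame({"sample_id": m.sample_ids, "z": z})
    return m, ann, {"genes": truth, "patients": truth_z}


def ffpe_like_cohort_annotation(n: int = 136, n_baseline_met: int = 3,
                                seed: int = 0) -> pd.DataFrame:
    """Clinical annotation shaped like a resected-NSCLC validation cohort.

    Defaults mirror the validation subset's composition: ``n`` patients
    of whom ``n_baseline_met`` carry a pre-existing metastasis at
    surgery (and are therefore excluded from MFS).  Times and events are
    random but deterministic given ``seed``; only the composition counts
    are fixed.
    """
    if n_baseline_met > n:
        raise ValueError("n_baseline_met cannot exceed n")
    rng = np.random.default_rng(seed)
    os_time = rng.uniform(1, 120, n)
    met_time = np.minimum(rng.uniform(1, 120, n), os_time)
    baseline = np.zeros(n, dtype=bool)
    baseline[rng.choice(n, n_baseline_met, replace=False)] = True
    return pd.DataFrame({
        "sample_id": [f"FFPE{i + 1:04d}" for i in range(n)],
        "os_time": os_time,
        "os_event": rng.integers(0, 2, n),
        "met_time": met_time,
        "met_event": rng.integers(0, 2, n),
        "baseline_metastasis": baseline,
        "stage": rng.choice(["IA", "IB", "II", "III", "IV"], n,
                            p=[0.40, 0.17, 0.16, 0.18, 0.09]),
    })


def simulate_two_arm_survival(n_per_arm: int = 150, hazard_ratio: float = 2.0,
                              baseline_hazard: float = 1.0 / 40.0,
                              censoring_fraction: float = 0.2,
                              seed: int = 0):
    """Two-arm exponential survival data for power checks.

    Arm B's hazard is ``hazard_ratio`` × arm A's.  Each subject is
    independently censored with probability ``censoring_fraction`` at a
    uniform time before its event.  Returns two (time, event) record
    DataFrames.
    """
    rng = np.random.default_rng(seed)

    def arm(h):
        t = rng.exponential(1.0 / h, n_per_arm)
        cens = rng.random(n_per_arm) < censoring_fraction
        t_obs = np.where(cens, rng.uniform(0, 1, n_per_arm) * t, t)
        return pd.DataFrame({"time": t_obs, "event": (~cens).astype(int)})

    return arm(baseline_hazard), arm(baseline_hazard * hazard_ratio)
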