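"""Synthetic cohorts with the statistical structure the pipeline assumes.

Gene baseline means are log-normal; read counts are negative binomial
with Var = mu + phi mu^2.  A chosen subset of TFs is "active": in the
tumour group the mean of each of their target genes is multiplied by
2^lfc, with optional per-sample heterogeneity in the effect.  Censored
survival times for tumour samples are exponential with a log-hazard
proportional to each sample's standardized true activity (plus an
optional purity term); purity itself is Beta-distributed.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ClinicalTable, CountMatrix, TFTargetCollection

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort",
           "simulate_shifted_samples", "simulate_survival_data",
           "truth_evaluation"]


@dataclass
class SimulationConfig:
    """Parameters of a simulated two-group RNA-seq cohort.

    Defaults describe a mid-sized paired-tissue design: 2000 genes, 20
    TFs with 50 targets each, 30 tumour vs 30 normal samples, NB
    dispersion 0.2 (typical bulk RNA-seq biological variability),
    log-normal baseline means around e^5 ~ 150 counts, and one active TF
    with a +1 log2 fold change on its targets.
    """

    n_genes: int = 2000
    n_tfs: int = 20
    targets_per_tf: int = 50
    n_tumour: int = 30
    n_normal: int = 30
    nb_dispersion: float = 0.2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    active_tfs: dict[str, float] = field(default_factory=lambda: {"TF01": 1.0})
    activity_sd: float = 0.3
    baseline_hazard: float = 1e-3
    activity_hazard_coef: float = 1.0
    censoring_rate: float = 1e-3
    purity_alpha: float = 4.3
    purity_beta: float = 1.41
    purity_hazard_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_per_tf > self.n_genes:
            raise ValueError("targets_per_tf cannot exceed n_genes")
        for name, val in (("nb_dispersion", self.nb_dispersion),
                          ("baseline_hazard", self.baseline_hazard)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.active_tfs) - set(self.tf_names)
        if bad:
            raise ValueError(f"active TFs not in the simulated TF universe: {sorted(bad)}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SimulationTruth:
    """What was planted: active TFs with their log2 fold changes and
    the realized per-tumour-sample activity (lfc x sample multiplier)."""

    active: dict[str, float]
    sample_activity: pd.DataFrame


@dataclass
class SimulatedCohort:
    counts: CountMatrix
    sets: TFTargetCollection
    clinical: ClinicalTable
    truth: SimulationTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort (counts + target sets + clinical table + truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    tumours = [f"T{i + 1:03d}" for i in range(cfg.n_tumour)]
    normals = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             size=cfg.n_genes)
    sets = {tf: set(rng.choice(genes, size=cfg.targets_per_tf, replace=False))
            for tf in cfg.tf_names}
    gene_index = {g: i for i, g in enumerate(genes)}

    # realized per-sample activity: lfc scaled by a noisy multiplier
    activity = pd.DataFrame(0.0, index=cfg.tf_names, columns=tumours)
    for tf, lfc in cfg.active_tfs.items():
        mult = rng.normal(1.0, cfg.activity_sd, size=cfg.n_tumour)
        activity.loc[tf] = lfc * mult

    counts = np.zeros((cfg.n_genes, cfg.n_tumour + cfg.n_normal), dtype=np.int64)
    for j in range(cfg.n_tumour):
        mean = baseline.copy()
        for tf in cfg.active_tfs:
            idx = [gene_index[g] for g in sets[tf]]
            mean[idx] = mean[idx] * 2.0 ** activity.loc[tf].iloc[j]
        counts[:, j] = _nb_draw(rng, mean, cfg.nb_dispersion)
    for j in range(cfg.n_normal):
        counts[:, cfg.n_tumour + j] = _nb_draw(rng, baseline, cfg.nb_dispersion)

    group = {s: "tumour" for s in tumours} | {s: "normal" for s in normals}
    cm = CountMatrix(gene_ids=genes, sample_ids=tumours + normals,
                     counts=counts, group=group)

    # survival for tumour samples, hazard tied to standardized activity
    total_act = activity.sum(axis=0).to_numpy()
    if total_act.std() > 0:
        z = (total_act - total_act.mean()) / total_act.std()
    else:
        z = np.zeros_like(total_act)
    purity = rng.beta(cfg.purity_alpha, cfg.purity_beta, size=cfg.n_tumour)
    log_hazard = (np.log(cfg.baseline_hazard) + cfg.activity_hazard_coef * z
                  + cfg.purity_hazard_coef * (purity - purity.mean()))
    death = rng.exponential(1.0 / np.exp(log_hazard))
    if cfg.censoring_rate > 0:
        censor = rng.exponential(1.0 / cfg.censoring_rate, size=cfg.n_tumour)
    else:
        censor = np.full(cfg.n_tumour, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    stage = rng.choice(["I", "II", "III", "IV"], size=cfg.n_tumour)
    clinical = ClinicalTable(pd.DataFrame(
        {"sample_id": tumours, "time": time, "event": event,
         "stage": stage, "purity": purity}))

    return SimulatedCohort(
        counts=cm,
        sets=TFTargetCollection(sets=sets, provenance=f"simulated(seed={cfg.seed})"),
        clinical=clinical,
        truth=SimulationTruth(active=dict(cfg.active_tfs),
                              sample_activity=activity))


def simulate_shifted_samples(n_genes: int = 2000, n_normal: int = 30,
                             n_tumour: int = 100, n_tfs: int = 20,
                             targets_per_tf: int = 50, shift_sd: float = 2.0,
                             planted_tf: str = "TF01", seed: int = 0
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        TFTargetCollection]:
    """Normalized-scale cohort for the per-sample activity layer.

    Normal and tumour samples are drawn around per-gene means with
    per-gene standard deviations; in every tumour sample the planted
    TF's targets are shifted up by ``shift_sd`` standard deviations.
    Returns (normals, tumours, collection) on the normalized log scale,
    ready for :func:`tftea.personalized.reference_profile`.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    mu = rng.normal(5.0, 2.0, n_genes)
    sd = rng.uniform(0.3, 1.0, n_genes)
    normals = pd.DataFrame(
        rng.normal(mu[:, None], sd[:, None], (n_genes, n_normal)),
        index=genes, columns=[f"N{i + 1:03d}" for i in range(n_normal)])
    sets = {f"TF{i + 1:02d}": set(rng.choice(genes, targets_per_tf, replace=False))
            for i in range(n_tfs)}
    if planted_tf not in sets:
        raise ValueError(f"planted TF {planted_tf!r} not among the simulated TFs")
    tum = rng.normal(mu[:, None], sd[:, None], (n_genes, n_tumour))
    gene_index = {g: i for i, g in enumerate(genes)}
    tidx = [gene_index[g] for g in sets[planted_tf]]
    tum[tidx, :] += shift_sd * sd[tidx][:, None]
    tumours = pd.DataFrame(
        tum, index=genes, columns=[f"T{i + 1:03d}" for i in range(n_tumour)])
    coll = TFTargetCollection(sets=sets, provenance=f"shifted(seed={seed})")
    return normals, tumours, coll


def simulate_survival_data(n: int, candidates: list[str],
                           coef: dict[str, float], baseline_hazard: float = 0.1,
                           censoring_rate: float = 0.05, seed: int = 0,
                           purity: bool = False
                           ) -> tuple[pd.DataFrame, ClinicalTable]:
    """Covariate-level survival simulation for the Cox layer.

    Candidate activities are i.i.d. standard normal per sample; event
    times are exponential with log-hazard = log(h0) + sum coef_v x_v,
    censored by an independent exponential.  Returns the activity matrix
    (TFs x samples) and the clinical table.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    X = pd.DataFrame(rng.standard_normal((len(candidates), n)),
                     index=candidates, columns=samples)
    lin = np.zeros(n)
    for v, c in coef.items():
        lin += c * X.loc[v].to_numpy()
    death = rng.exponential(1.0 / (baseline_hazard * np.exp(lin)))
    censor = (rng.exponential(1.0 / censoring_rate, size=n)
              if censoring_rate > 0 else np.full(n, np.inf))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    data = {"sample_id": samples, "time": time, "event": event}
    if purity:
        data["purity"] = rng.beta(4.3, 1.41, size=n)
    return X, ClinicalTable(pd.DataFrame(data))


def truth_evaluation(results, truth: SimulationTruth, alpha: float = 0.05) -> dict:
    """Sensitivity and empirical FDR of a result set against the truth.

    Accepts either a list of per-TF enrichment results (cohort level) or
    a per-sample activity matrix.  A discovery is a tested entry with
    adjusted p below ``alpha``; it is a true positive when the TF was
    planted active and the reported direction matches the sign of the
    planted fold change.  With no discoveries the FDR is defined as 0.
    """
    from .personalized import SampleActivityMatrix

    active = truth.active
    if isinstance(results, SampleActivityMatrix):
        if set(results.tf_names) != set(truth.sample_activity.index):
            raise ValueError("TF universes of results and truth differ")
        tp = fp = fn = 0
        for s in results.sample_ids:
            for tf in results.tf_names:
                adj = results.adj_p.loc[tf, s]
                sig = (not np.isnan(adj)) and adj < alpha
                planted = tf in active and truth.sample_activity.loc[tf, s] != 0
                if sig:
                    good_sign = planted and (
                        np.sign(results.activity.loc[tf, s])
                        == np.sign(truth.sample_activity.loc[tf, s]))
                    if good_sign:
                        tp += 1
                    else:
                        fp += 1
                elif planted:
                    fn += 1
    else:
        result_tfs = {r.tf_name for r in results}
        if not set(active) <= result_tfs:
            raise ValueError("TF universes of results and truth differ")
        tp = fp = fn = 0
        for r in results:
            sig = r.tested and r.adj_p < alpha
            planted = r.tf_name in active
            if sig:
                if planted and r.direction == np.sign(active[r.tf_name]):
                    tp += 1
                else:
                    fp += 1
            elif planted:
                fn += 1
    n_disc = tp + fp
    return {"tp": tp, "fp": fp, "fn": fn,
            "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
            "fdr": fp / n_disc if n_disc else 0.0}
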