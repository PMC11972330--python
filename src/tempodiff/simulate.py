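"""Synthetic two-condition expression time courses with ground truth.

Emulates a bulk RNA-seq time course run in two genotypes (WT and KO) over a
shared grid of time points, with a small planted fraction of genes whose KO
trajectory diverges from WT (delayed, attenuated, suppressed or ectopic
activation — the trajectory shapes seen for sequentially activated
developmental genes). All remaining genes share one latent trajectory between
conditions, so any distance between their WT and KO series is pure noise.

Two emission modes:

``counts``
    Latent per-gene TPM trajectories are converted to expected read counts
    (proportional to TPM x gene length, scaled to a lognormal library size)
    and emitted as negative-binomial counts. Exercises the TPM/log pipeline.
``expression``
    Gaussian noise is added directly on the log2(TPM+1) scale and the matrix
    holds expression values. Exercises the screen in isolation; with
    ``noise_sd_log=0`` null genes have exactly identical WT/KO series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._errors import ConfigError

__all__ = ["SimulationConfig", "SimulationResult", "simulate_timecourse"]

#: Reconstructed default sampling days for a 7-point, day 0-14 design.
DEFAULT_TIME_VECTOR = (0.0, 2.0, 4.0, 6.0, 9.0, 11.0, 14.0)

EFFECT_KINDS = ("delay", "attenuation", "suppression", "ectopic")
TEMPLATES = ("flat", "ramp", "pulse", "sigmoid")

# Template mixture for null genes: mostly flat housekeeping-like profiles,
# the rest split across monotone and transient dynamic shapes.
_NULL_TEMPLATE_PROBS = {"flat": 0.60, "sigmoid": 0.15, "ramp": 0.15, "pulse": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic time-course generator.

    Defaults mirror the emulated study design: 7 time points spanning two
    weeks, 4 WT and 2 KO replicates (clones), log2(TPM+1) expression scale.
    """

    n_genes: int = 2000
    n_timepoints: int = 7
    time_vector: tuple[float, ...] = DEFAULT_TIME_VECTOR
    replicates_wt: int = 4
    replicates_ko: int = 2
    n_differential: int = 0
    effect_kinds: tuple[str, ...] = EFFECT_KINDS
    delay_shift: float = 4.0  # days; activation midpoint shift for "delay"
    attenuation_factor: float = 0.3  # linear-scale plateau multiplier
    noise_sd_log: float = 0.1  # Gaussian sd on log2 expression
    nb_dispersion: float = 10.0  # NB size parameter; var = mu + mu^2/size
    mean_library_size: float = 2e7  # reads; lognormal, cv 0.2
    gene_length_log_mean: float = math.log(1500.0)  # bp, lognormal
    gene_length_log_sd: float = 0.6
    emission_mode: str = "counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        tv = np.asarray(self.time_vector, dtype=float)
        if tv.size != self.n_timepoints:
            raise ConfigError(
                f"time_vector has length {tv.size}, expected n_timepoints={self.n_timepoints}"
            )
        if not np.all(np.diff(tv) > 0):
            raise ConfigError("time_vector must be strictly increasing")
        if self.replicates_wt <= 0 or self.replicates_ko <= 0:
            raise ConfigError("replicate counts must be positive")
        if not 0 <= self.n_differential <= self.n_genes:
            raise ConfigError(
                f"n_differential={self.n_differential} must be in [0, n_genes={self.n_genes}]"
            )
        unknown = set(self.effect_kinds) - set(EFFECT_KINDS)
        if unknown:
            raise ConfigError(
                f"unknown effect kinds {sorted(unknown)}; valid: {list(EFFECT_KINDS)}"
            )
        if self.n_differential > 0 and not self.effect_kinds:
            raise ConfigError("effect_kinds must be non-empty when n_differential > 0")
        if self.delay_shift < 0:
            raise ConfigError("delay_shift must be >= 0")
        if not 0 < self.attenuation_factor < 1:
            raise ConfigError("attenuation_factor must be in (0, 1)")
        if self.noise_sd_log < 0:
            raise ConfigError("noise_sd_log must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.mean_library_size <= 0:
            raise ConfigError("mean_library_size must be positive")
        if self.emission_mode not in ("counts", "expression"):
            raise ConfigError("emission_mode must be 'counts' or 'expression'")


class SimulationResult(NamedTuple):
    """Output bundle: data matrix, gene lengths, sample sheet, truth table."""

    matrix: pd.DataFrame  # genes x samples; integer counts or float expression
    gene_lengths: pd.Series  # bp, indexed by gene_id
    sample_sheet: pd.DataFrame  # sample_id, condition, timepoint, replicate
    truth: pd.DataFrame  # per-gene ground truth


def _sigmoid(t: np.ndarray, baseline: float, amplitude: float, onset: float, k: float) -> np.ndarray:
    return baseline + amplitude / (1.0 + np.exp(-k * (t - onset)))


def _latent_tpm(
    template: str,
    t: np.ndarray,
    baseline: float,
    amplitude: float,
    onset: float,
    width: float,
) -> np.ndarray:
    """Noise-free TPM trajectory on the linear scale."""
    if template == "flat":
        return np.full_like(t, baseline)
    if template == "sigmoid":
        return _sigmoid(t, baseline, amplitude, onset, k=1.0)
    if template == "ramp":
        span = t[-1] - t[0]
        return baseline + amplitude * np.clip((t - t[0]) / span, 0.0, 1.0)
    if template == "pulse":
        return baseline + amplitude * np.exp(-0.5 * ((t - onset) / width) ** 2)
    raise ConfigError(f"unknown template {template!r}")


def simulate_timecourse(config: SimulationConfig) -> SimulationResult:
    """Generate a synthetic two-condition time course with ground truth.

    Deterministic for a fixed ``config.seed``. Null genes share one latent
    trajectory between WT and KO; planted genes modify the KO trajectory
    according to their effect kind:

    - ``delay``: the whole KO trajectory is evaluated at ``t - delay_shift``
      (activation midpoint shifted later);
    - ``attenuation``: KO amplitude multiplied by ``attenuation_factor`` on
      the linear TPM scale;
    - ``suppression``: KO flattened to its baseline;
    - ``ectopic``: WT is flat at baseline while KO activates.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.time_vector, dtype=float)
    n = config.n_genes
    n_digits = max(4, len(str(n)))
    gene_ids = [f"G{i:0{n_digits}d}" for i in range(n)]

    lengths = np.round(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, size=n)
    ).astype(int)
    lengths = np.maximum(lengths, 200)  # floor: no implausibly short transcripts
    gene_lengths = pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"), name="length_bp")

    # --- per-gene latent trajectories -------------------------------------
    diff_idx = rng.choice(n, size=config.n_differential, replace=False)
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    effect_cycle = np.array(
        [config.effect_kinds[i % len(config.effect_kinds)] for i in range(config.n_differential)]
        if config.n_differential
        else [],
        dtype=object,
    )

    null_templates = rng.choice(
        list(_NULL_TEMPLATE_PROBS), size=n, p=list(_NULL_TEMPLATE_PROBS.values())
    )

    baseline = rng.uniform(0.5, 5.0, size=n)
    amplitude = np.exp(rng.uniform(np.log(10.0), np.log(1000.0), size=n))
    onset = rng.uniform(t[0] + 2.0, t[-1] - 4.0, size=n)
    width = rng.uniform(1.5, 3.0, size=n)

    wt_latent = np.empty((n, t.size))
    ko_latent = np.empty((n, t.size))
    templates = np.empty(n, dtype=object)
    effects = np.full(n, "", dtype=object)

    diff_rank = 0
    for g in range(n):
        if is_diff[g]:
            effect = effect_cycle[diff_rank]
            diff_rank += 1
            effects[g] = effect
            templates[g] = "sigmoid"
            if effect == "ectopic":
                templates[g] = "flat"  # WT stays flat; KO activates
                wt_latent[g] = np.full_like(t, baseline[g])
                ko_latent[g] = _sigmoid(t, baseline[g], amplitude[g], onset[g], k=1.0)
            elif effect == "delay":
                wt_latent[g] = _sigmoid(t, baseline[g], amplitude[g], onset[g], k=1.0)
                ko_latent[g] = _sigmoid(
                    t - config.delay_shift, baseline[g], amplitude[g], onset[g], k=1.0
                )
            elif effect == "attenuation":
                wt_latent[g] = _sigmoid(t, baseline[g], amplitude[g], onset[g], k=1.0)
                ko_latent[g] = _sigmoid(
                    t, baseline[g], amplitude[g] * config.attenuation_factor, onset[g], k=1.0
                )
            else:  # suppression
                wt_latent[g] = _sigmoid(t, baseline[g], amplitude[g], onset[g], k=1.0)
                ko_latent[g] = np.full_like(t, baseline[g])
        else:
            templates[g] = null_templates[g]
            traj = _latent_tpm(
                templates[g], t, baseline[g], amplitude[g], onset[g], width[g]
            )
            wt_latent[g] = traj
            ko_latent[g] = traj

    # --- sample layout -----------------------------------------------------
    rows = []
    for cond, n_rep in (("WT", config.replicates_wt), ("KO", config.replicates_ko)):
        for rep in range(1, n_rep + 1):
            for tp in t:
                rows.append(
                    {
                        "sample_id": f"{cond}_d{tp:g}_r{rep}",
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    sample_sheet = pd.DataFrame(rows)
    sample_ids = sample_sheet["sample_id"].tolist()
    tp_index = {tp: i for i, tp in enumerate(t)}

    # --- emission ----------------------------------------------------------
    n_samples = len(sample_sheet)
    if config.emission_mode == "expression":
        matrix = np.empty((n, n_samples))
        for j, row in enumerate(sample_sheet.itertuples(index=False)):
            latent = wt_latent if row.condition == "WT" else ko_latent
            col = np.log2(latent[:, tp_index[row.timepoint]] + 1.0)
            if config.noise_sd_log > 0:
                col = col + rng.normal(0.0, config.noise_sd_log, size=n)
            matrix[:, j] = col
        data = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    else:
        lib_sizes = rng.lognormal(
            np.log(config.mean_library_size) - 0.5 * np.log(1 + 0.2**2),
            np.sqrt(np.log(1 + 0.2**2)),
            size=n_samples,
        )
        len_kb = lengths / 1000.0
        matrix = np.empty((n, n_samples), dtype=np.int64)
        for j, row in enumerate(sample_sheet.itertuples(index=False)):
            latent = wt_latent if row.condition == "WT" else ko_latent
            tpm = latent[:, tp_index[row.timepoint]].copy()
            if config.noise_sd_log > 0:
                tpm = tpm * np.exp2(rng.normal(0.0, config.noise_sd_log, size=n))
            weights = tpm * len_kb
            mu = lib_sizes[j] * weights / weights.sum()
            lam = rng.gamma(config.nb_dispersion, mu / config.nb_dispersion)
            matrix[:, j] = rng.poisson(lam)
        data = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    data.index.name = "gene_id"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_differential": is_diff,
            "effect_kind": effects,
            "template": templates,
            "baseline_tpm": baseline,
            "amplitude_tpm": amplitude,
            "onset_day": onset,
            "width_days": width,
        }
    )
    return SimulationResult(data, gene_lengths, sample_sheet, truth)
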