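"""Synthetic data generators for every analysis stage in the package.

Each generator emulates the statistical structure of one input the pipeline
consumes — negative-binomial spectral counts for the sorted-synaptosome vs
reference comparison, 384-well plate OD650 matrices for the extracellular
interactome screen, spectral-count pull-down tables, and steady-state
biolayer-interferometry concentration series — and always returns ground-truth
labels alongside the data, so downstream recovery tests never have to
re-derive truth from the simulated measurements.

All generators are deterministic given their config (including the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bli import BindingSeries

GROUP_MF = "MF"
GROUP_P2 = "P2"
CONTROL_BAIT = "AP-only"
BLANK_LABEL = "BLANK"

__all__ = [
    "CountSimConfig",
    "ScreenSimConfig",
    "BliSimConfig",
    "ScreenExperiment",
    "gen_spectral_counts",
    "gen_elisa_screen",
    "gen_pulldown",
    "gen_bli_series",
    "write_counts_tsv",
    "write_screen_tsv",
    "write_pulldown_tsv",
    "write_bli_tsv",
]


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid {field_name}: {message}")


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the spectral-count simulator (3-vs-3 design by default).

    ``baseline_mean`` is the expected spectral count of an average protein in
    the reference group; ``dispersion`` is the negative-binomial size
    parameter k (variance = mu + mu^2/k, smaller k = noisier counts).
    """

    seed: int
    n_proteins: int = 1000
    n_replicates_per_group: int = 3
    length_range_aa: tuple[int, int] = (100, 2000)
    baseline_mean: float = 10.0
    dispersion: float = 10.0
    n_enriched: int = 0
    enrichment_fold: float = 8.0
    n_exclusive: int = 0
    detect_dropout: float = 0.0

    def validate(self) -> None:
        _require(self.n_proteins > 0, "n_proteins", "must be positive")
        _require(self.n_replicates_per_group >= 2, "n_replicates_per_group",
                 "need at least 2 replicates per group")
        lo, hi = self.length_range_aa
        _require(0 < lo <= hi, "length_range_aa", "must satisfy 0 < lo <= hi")
        _require(self.baseline_mean > 0, "baseline_mean", "must be positive")
        _require(self.dispersion > 0, "dispersion", "must be positive")
        _require(self.n_enriched >= 0, "n_enriched", "must be non-negative")
        _require(self.n_exclusive >= 0, "n_exclusive", "must be non-negative")
        _require(self.enrichment_fold > 0, "enrichment_fold", "must be positive")
        _require(self.n_enriched + self.n_exclusive <= self.n_proteins,
                 "n_enriched", "n_enriched + n_exclusive exceeds n_proteins")
        _require(0.0 <= self.detect_dropout <= 1.0, "detect_dropout",
                 "must be a probability in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size ``k``."""
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def gen_spectral_counts(config: CountSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-protein spectral/peptide count table for two groups.

    Returns ``(table, truth)``. ``table`` has columns ``protein_id``,
    ``length_aa``, then ``spc_<group>_<rep>`` and ``pep_<group>_<rep>`` for
    groups MF (sorted mossy-fiber synaptosomes) and P2 (crude reference
    synaptosomes). ``truth`` labels each protein ``null``, ``enriched``
    (MF mean = enrichment_fold x baseline) or ``exclusive`` (all P2 counts
    zero, nonzero MF counts).

    Peptide counts are derived as ceil(SpC/2), floored at 1 wherever a
    spectral count was observed: only the summed-peptide detection filter
    consumes them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, r = config.n_proteins, config.n_replicates_per_group

    protein_ids = np.array([f"PROT{i:05d}" for i in range(n)])
    lengths = rng.integers(config.length_range_aa[0],
                           config.length_range_aa[1] + 1, size=n)

    # Per-protein abundance spread around the baseline (lognormal, median =
    # baseline_mean) mimics the wide dynamic range of spectral counts.
    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=n)

    status = np.array(["null"] * n, dtype=object)
    idx = rng.permutation(n)
    enriched_idx = idx[: config.n_enriched]
    exclusive_idx = idx[config.n_enriched: config.n_enriched + config.n_exclusive]
    status[enriched_idx] = "enriched"
    status[exclusive_idx] = "exclusive"

    mf_mean = base.copy()
    mf_mean[enriched_idx] *= config.enrichment_fold
    mf_mean[exclusive_idx] = np.maximum(base[exclusive_idx], 2.0)
    p2_mean = base.copy()

    mf = _nb_draw(rng, np.tile(mf_mean[:, None], (1, r)), config.dispersion)
    p2 = _nb_draw(rng, np.tile(p2_mean[:, None], (1, r)), config.dispersion)

    if config.detect_dropout > 0:
        mf *= rng.random(mf.shape) >= config.detect_dropout
        p2 *= rng.random(p2.shape) >= config.detect_dropout

    p2[exclusive_idx, :] = 0
    # Exclusive proteins must be detected in at least one MF replicate.
    zero_rows = exclusive_idx[mf[exclusive_idx].sum(axis=1) == 0]
    if zero_rows.size:
        mf[zero_rows, rng.integers(0, r, size=zero_rows.size)] = 1

    pep_mf = np.where(mf > 0, np.maximum(np.ceil(mf / 2).astype(int), 1), 0)
    pep_p2 = np.where(p2 > 0, np.maximum(np.ceil(p2 / 2).astype(int), 1), 0)

    data: dict[str, np.ndarray] = {"protein_id": protein_ids,
                                   "length_aa": lengths}
    for j in range(r):
        data[f"spc_{GROUP_MF}_{j + 1}"] = mf[:, j]
    for j in range(r):
        data[f"spc_{GROUP_P2}_{j + 1}"] = p2[:, j]
    for j in range(r):
        data[f"pep_{GROUP_MF}_{j + 1}"] = pep_mf[:, j]
    for j in range(r):
        data[f"pep_{GROUP_P2}_{j + 1}"] = pep_p2[:, j]
    table = pd.DataFrame(data)

    truth = pd.DataFrame({"protein_id": protein_ids, "status": status})
    return table, truth


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of the plate-screen simulator.

    Defaults reproduce the screen's stated design: 73 ectodomain constructs
    tested AP-bait x Fc-prey in both orientations over three independent
    experiments, background OD650 of 0.07 +/- 0.027 estimated from 100 blank
    wells, and positives reaching up to ~50-fold over background.
    """

    seed: int
    n_constructs: int = 73
    n_experiments: int = 3
    true_pairs: tuple[tuple[int, int], ...] = ()
    bg_mean: float = 0.07
    bg_sd: float = 0.027
    max_fob: float = 50.0
    n_blanks: int = 100
    n_sticky_preys: int = 0
    detection_prob: float = 0.95

    def validate(self) -> None:
        _require(self.n_constructs > 0, "n_constructs", "must be positive")
        _require(self.n_experiments > 0, "n_experiments", "must be positive")
        _require(self.bg_mean > 0, "bg_mean", "must be positive")
        _require(self.bg_sd >= 0, "bg_sd", "must be non-negative")
        _require(self.max_fob > 6, "max_fob", "must exceed the sticky floor of 6")
        _require(self.n_blanks >= 30, "n_blanks",
                 "at least 30 blank wells are required to estimate background")
        _require(0 <= self.n_sticky_preys <= self.n_constructs,
                 "n_sticky_preys", "must be within [0, n_constructs]")
        _require(0.0 <= self.detection_prob <= 1.0, "detection_prob",
                 "must be a probability in [0, 1]")
        for a, b in self.true_pairs:
            _require(0 <= a < self.n_constructs and 0 <= b < self.n_constructs,
                     "true_pairs", "construct index out of range")


@dataclass
class ScreenExperiment:
    """One plate experiment: an Fc-prey x AP-bait OD650 matrix plus blanks.

    Columns are AP baits (the construct set plus one AP-only negative-control
    column); rows are Fc preys (the construct set). ``od`` is a DataFrame
    indexed by prey label with bait labels as columns.
    """

    experiment_id: str
    od: pd.DataFrame
    blank_values: np.ndarray
    control_bait: str = CONTROL_BAIT

    def __post_init__(self) -> None:
        if self.control_bait not in self.od.columns:
            raise ValueError(
                f"control bait column {self.control_bait!r} missing from OD matrix")
        if len(self.blank_values) < 30:
            raise ValueError(
                "at least 30 blank wells are required (plate minimum)")
        if (self.od.values < 0).any() or (np.asarray(self.blank_values) < 0).any():
            raise ValueError("OD650 values must be non-negative")

    @property
    def bait_labels(self) -> list[str]:
        return [c for c in self.od.columns if c != self.control_bait]

    @property
    def prey_labels(self) -> list[str]:
        return list(self.od.index)


def construct_labels(n: int) -> list[str]:
    return [f"C{i + 1:03d}" for i in range(n)]


def gen_elisa_screen(config: ScreenSimConfig) -> tuple[list[ScreenExperiment], dict]:
    """Simulate the bait x prey ELISA screen over independent experiments.

    Per experiment the OD matrix has one row per Fc prey and one column per
    AP bait plus the AP-only control column. Background wells draw from a
    truncated normal (clipped at 0). A planted true pair {X, Y} yields a
    strong signal (uniform FOB in [6, max_fob] times the background mean) in
    each of its orientations with probability ``detection_prob``; a homophilic
    pair has a single diagonal well per experiment. Sticky (promiscuous)
    preys exceed threshold against every bait including the control.

    Returns the experiments plus a truth dict with ``true_pairs`` (label
    pairs) and ``sticky_preys`` (labels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_constructs
    labels = construct_labels(n)
    baits = labels + [CONTROL_BAIT]

    sticky_idx = rng.choice(n, size=config.n_sticky_preys, replace=False)
    experiments: list[ScreenExperiment] = []

    for e in range(config.n_experiments):
        od = np.clip(rng.normal(config.bg_mean, config.bg_sd, size=(n, n + 1)),
                     0.0, None)
        for a, b in config.true_pairs:
            # Orientation AP-a / Fc-b: bait column a, prey row b.
            for bait, prey in ({(a, b), (b, a)} if a != b else {(a, a)}):
                if rng.random() < config.detection_prob:
                    od[prey, bait] = (config.bg_mean
                                      * rng.uniform(6.0, config.max_fob))
        for prey in sticky_idx:
            od[prey, :] = config.bg_mean * rng.uniform(6.0, config.max_fob,
                                                       size=n + 1)
        blanks = np.clip(rng.normal(config.bg_mean, config.bg_sd,
                                    size=config.n_blanks), 0.0, None)
        experiments.append(ScreenExperiment(
            experiment_id=f"exp{e + 1}",
            od=pd.DataFrame(od, index=labels, columns=baits),
            blank_values=blanks,
        ))

    truth = {
        "true_pairs": sorted(tuple(sorted((labels[a], labels[b])))
                             for a, b in config.true_pairs),
        "sticky_preys": sorted(labels[i] for i in sticky_idx),
    }
    return experiments, truth


def gen_pulldown(seed: int,
                 n_proteins: int = 50,
                 n_bait_experiments: int = 2,
                 hit_fraction: float = 0.1,
                 contaminant_fraction: float = 0.2,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an ecto-Fc pull-down spectral-count table with one Fc control.

    True hits carry >=2 spectral counts in every bait experiment and 0 or 1
    in the Fc control; contaminants carry counts in bait and control alike;
    the remaining background proteins have sparse low counts. Returns
    ``(table, truth)`` where truth labels each protein hit / contaminant /
    background.
    """
    if not (0.0 <= hit_fraction <= 1.0 and 0.0 <= contaminant_fraction <= 1.0):
        raise ValueError("hit_fraction and contaminant_fraction must be in [0, 1]")
    if hit_fraction + contaminant_fraction > 1.0:
        raise ValueError("hit_fraction + contaminant_fraction must not exceed 1")
    if n_proteins <= 0 or n_bait_experiments <= 0:
        raise ValueError("n_proteins and n_bait_experiments must be positive")

    rng = np.random.default_rng(seed)
    n_hits = int(round(hit_fraction * n_proteins))
    n_cont = int(round(contaminant_fraction * n_proteins))

    status = np.array(["background"] * n_proteins, dtype=object)
    order = rng.permutation(n_proteins)
    status[order[:n_hits]] = "hit"
    status[order[n_hits:n_hits + n_cont]] = "contaminant"

    bait = np.zeros((n_proteins, n_bait_experiments), dtype=int)
    ctrl = np.zeros(n_proteins, dtype=int)
    for i in range(n_proteins):
        if status[i] == "hit":
            bait[i] = 2 + rng.poisson(4.0, size=n_bait_experiments)
            ctrl[i] = rng.integers(0, 2)  # 0 or 1
        elif status[i] == "contaminant":
            bait[i] = 1 + rng.poisson(5.0, size=n_bait_experiments)
            ctrl[i] = 2 + rng.poisson(4.0)
        else:
            bait[i] = rng.poisson(0.5, size=n_bait_experiments)
            ctrl[i] = rng.poisson(0.5)

    data: dict[str, np.ndarray] = {
        "protein_id": np.array([f"PD{i:04d}" for i in range(n_proteins)])}
    for j in range(n_bait_experiments):
        data[f"spc_bait_{j + 1}"] = bait[:, j]
    data["spc_ctrl_1"] = ctrl
    table = pd.DataFrame(data)
    truth = pd.DataFrame({"protein_id": data["protein_id"], "status": status})
    return table, truth


@dataclass(frozen=True)
class BliSimConfig:
    """Parameters of the steady-state BLI simulator.

    The default ladder is the screen's printed series: 34 uM diluted twofold
    nine times down to ~0.133 uM. Responses follow the one-site saturation
    model R(C) = rmax_true * C / (kd_true + C) with additive Gaussian noise
    and an optional linear drift along the dilution index.
    """

    seed: int
    kd_true: float = 1.4
    rmax_true: float = 1.0
    top_concentration: float = 34.0
    n_dilutions: int = 9
    noise_sd: float = 0.02
    drift_slope: float = 0.0

    def validate(self) -> None:
        _require(self.kd_true > 0, "kd_true", "must be positive")
        _require(self.rmax_true > 0, "rmax_true", "must be positive")
        _require(self.top_concentration > 0, "top_concentration",
                 "must be positive")
        _require(self.n_dilutions >= 2, "n_dilutions", "need at least 2 points")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")


def gen_bli_series(config: BliSimConfig) -> BindingSeries:
    """Simulate one steady-state concentration-response series.

    One response per concentration of the twofold dilution ladder, plus a
    buffer-only zero point carrying noise (and drift) alone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conc = config.top_concentration / (2.0 ** np.arange(config.n_dilutions))
    resp = config.rmax_true * conc / (config.kd_true + conc)
    resp = resp + config.drift_slope * np.arange(config.n_dilutions)
    resp = resp + rng.normal(0.0, config.noise_sd, size=config.n_dilutions)
    buffer_resp = float(rng.normal(0.0, config.noise_sd))
    return BindingSeries(concentrations=conc, responses=resp,
                         buffer_response=buffer_resp)


# --- TSV / JSON sidecar writers ---------------------------------------------

def _write_sidecar(path: Path, config, truth) -> None:
    payload = {"config": asdict(config) if hasattr(config, "__dataclass_fields__")
               else config}
    if isinstance(truth, pd.DataFrame):
        payload["truth"] = truth.to_dict(orient="list")
    else:
        payload["truth"] = truth
    path.write_text(json.dumps(payload, indent=2, default=str))


def write_counts_tsv(table: pd.DataFrame, truth: pd.DataFrame,
                     config: CountSimConfig, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "spectral_counts.tsv"
    table.to_csv(path, sep="\t", index=False)
    _write_sidecar(out_dir / "spectral_counts.json", config, truth)
    return path


def write_screen_tsv(experiments: list[ScreenExperiment], truth: dict,
                     config: ScreenSimConfig, out_dir: Path) -> list[Path]:
    """Write each experiment as long-format TSV (blanks as BLANK/BLANK rows)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for exp in experiments:
        rows = [
            {"experiment_id": exp.experiment_id, "bait": bait, "prey": prey,
             "od650": exp.od.at[prey, bait]}
            for bait in exp.od.columns for prey in exp.od.index
        ]
        rows.extend(
            {"experiment_id": exp.experiment_id, "bait": BLANK_LABEL,
             "prey": BLANK_LABEL, "od650": v} for v in exp.blank_values)
        path = out_dir / f"screen_{exp.experiment_id}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
    _write_sidecar(out_dir / "screen.json", config, truth)
    return paths


def write_pulldown_tsv(table: pd.DataFrame, truth: pd.DataFrame,
                       params: dict, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "pulldown.tsv"
    table.to_csv(path, sep="\t", index=False)
    _write_sidecar(out_dir / "pulldown.json", params, truth)
    return path


def write_bli_tsv(series: BindingSeries, config: BliSimConfig,
                  out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "bli_series.tsv"
    df = pd.DataFrame({"concentration_uM": series.concentrations,
                       "response_nm": series.responses})
    if series.buffer_response is not None:
        df = pd.concat([df, pd.DataFrame({"concentration_uM": [0.0],
                                          "response_nm": [series.buffer_response]})],
                       ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
    _write_sidecar(out_dir / "bli_series.json", config,
                   {"kd_true": config.kd_true, "rmax_true": config.rmax_true})
    return path
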