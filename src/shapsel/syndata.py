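"""Synthetic multiscale expression data with planted class signal.

Values are log-normal (Gaussian on the log2 scale, exponentiated), giving
nonnegative right-skewed FPKM-like measurements. A configurable subset of
features in each block carries a standardized class-mean shift on the log
scale, with planted directions alternating up/down by feature index so
direction-aware selection is exercisable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io_prep import (
    ConfigError,
    ExpressionBlock,
    FormatError,
    SampleLabels,
    substream,
    write_expression,
    write_labels,
)


@dataclass
class SynthConfig:
    n_samples: int = 200
    class_balance: float = 0.75
    n_mrna: int = 2000
    n_mirna: int = 300
    n_informative_mrna: int = 50
    n_informative_mirna: int = 10
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 < self.class_balance < 1:
            raise ConfigError(f"class_balance must be in (0,1), got {self.class_balance}")
        if self.n_informative_mrna > self.n_mrna or self.n_informative_mrna < 0:
            raise ConfigError(
                f"n_informative_mrna must be in [0, n_mrna], got {self.n_informative_mrna}"
            )
        if self.n_informative_mirna > self.n_mirna or self.n_informative_mirna < 0:
            raise ConfigError(
                f"n_informative_mirna must be in [0, n_mirna], got {self.n_informative_mirna}"
            )
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping: which features carry class signal and
    in which direction (+1 up / -1 down in the positive class)."""

    informative: dict[str, set[str]] = field(default_factory=dict)  # block tag -> feature ids
    direction: dict[str, int] = field(default_factory=dict)  # feature id -> +1/-1

    def all_informative(self) -> set[str]:
        return set().union(*self.informative.values()) if self.informative else set()


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _make_block(
    tag: str,
    prefix: str,
    n_features: int,
    n_informative: int,
    y: np.ndarray,
    cfg: SynthConfig,
    rng_place: np.random.Generator,
    rng_vals: np.random.Generator,
    truth: GroundTruth,
) -> ExpressionBlock:
    fids = _feature_ids(prefix, n_features)
    baseline = rng_vals.uniform(2.0, 10.0, size=n_features)
    informative_idx = np.sort(rng_place.choice(n_features, size=n_informative, replace=False))
    delta = np.zeros(n_features)
    shift = cfg.effect_size * cfg.noise_sd
    truth.informative[tag] = set()
    for j, idx in enumerate(informative_idx):
        direction = 1 if j % 2 == 0 else -1  # alternate up/down deterministically
        delta[idx] = direction * shift
        truth.informative[tag].add(fids[idx])
        truth.direction[fids[idx]] = direction
    # class means straddle the baseline so non-informative marginals are unchanged
    mu = baseline[:, None] + delta[:, None] * (y[None, :] - 0.5)
    log_vals = mu + cfg.noise_sd * rng_vals.standard_normal((n_features, len(y)))
    return ExpressionBlock(fids, _sample_ids(len(y)), np.exp2(log_vals), tag)


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionBlock, ExpressionBlock, SampleLabels, GroundTruth]:
    """Generate one dataset: mRNA block, miRNA block, labels and ground truth.

    Deterministic given ``config.seed``; label assignment, feature
    placement and value noise each draw from a named sub-stream of the
    global seed so stages can be re-run independently.
    """
    n_pos = int(round(config.n_samples * config.class_balance))
    n_pos = min(max(n_pos, 1), config.n_samples - 1)  # both classes always present
    y = np.zeros(config.n_samples, dtype=int)
    y[:n_pos] = 1
    y = y[substream(config.seed, "labels").permutation(config.n_samples)]
    labels = SampleLabels(_sample_ids(config.n_samples), y)

    truth = GroundTruth()
    rng_place = substream(config.seed, "placement")
    rng_vals = substream(config.seed, "values")
    mrna = _make_block(
        "mRNA", "gene", config.n_mrna, config.n_informative_mrna, y, config, rng_place, rng_vals, truth
    )
    mirna = _make_block(
        "miRNA", "mir", config.n_mirna, config.n_informative_mirna, y, config, rng_place, rng_vals, truth
    )
    return mrna, mirna, labels, truth


def write_fixture(
    blocks: list[ExpressionBlock],
    labels: SampleLabels,
    truth: GroundTruth,
    directory: str | os.PathLike,
) -> dict[str, str]:
    """Write a dataset as tab-delimited files plus a ground-truth sidecar.

    Round-trips losslessly through :mod:`shapsel.io_prep` readers within
    numeric text precision.
    """
    if labels.n_samples == 0:
        raise FormatError("refusing to write a fixture with an empty sample set")
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for b in blocks:
        p = os.path.join(directory, f"{b.block.lower()}_expression.tsv")
        write_expression(b, p)
        paths[b.block] = p
    lp = os.path.join(directory, "labels.tsv")
    write_labels(labels, lp)
    paths["labels"] = lp
    tp = os.path.join(directory, "ground_truth.tsv")
    with open(tp, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tblock\tinformative\tdirection\n")
        for b in blocks:
            for fid in b.feature_ids:
                info = fid in truth.informative.get(b.block, set())
                fh.write(f"{fid}\t{b.block}\t{int(info)}\t{truth.direction.get(fid, 0):+d}\n")
    paths["ground_truth"] = tp
    return paths


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    truth = GroundTruth()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["feature_id", "block", "informative", "direction"]:
            raise FormatError(f"{path}: unexpected ground-truth header {header}")
        for line in fh:
            fid, block, info, direction = line.rstrip("\n").split("\t")
            truth.informative.setdefault(block, set())
            if int(info):
                truth.informative[block].add(fid)
                truth.direction[fid] = int(direction)
    return truth
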