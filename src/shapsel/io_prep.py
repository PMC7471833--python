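"""Reading, normalization, filtering and splitting of expression blocks.

The tabular dialect is tab-delimited UTF-8: expression matrices carry a
``feature_id`` header cell followed by sample ids, one row per feature;
label files carry ``sample_id`` and ``label`` columns.
"""

from __future__ import annotations

import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

BLOCK_TAGS = ("mRNA", "miRNA", "combined")
NORMALIZATION_METHODS = ("log2_zscore", "log2", "none")

POSITIVE, NEGATIVE = "positive", "negative"


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single global seed.

    Uses a CRC32 of the stream name so the mapping is stable across
    processes (unlike the builtin string hash).
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class ExpressionBlock:
    """One feature-block matrix, features x samples.

    Raw blocks hold nonnegative FPKM-like values; normalized blocks may
    hold any real values.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    block: str

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.block not in BLOCK_TAGS:
            raise ValueError(f"unknown block tag {self.block!r}; expected one of {BLOCK_TAGS}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {kind} ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids) -> "ExpressionBlock":
        idx = self.sample_index(sample_ids)
        return ExpressionBlock(self.feature_ids, list(sample_ids), self.values[:, idx], self.block)

    def subset_features(self, feature_ids) -> "ExpressionBlock":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        idx = np.array([pos[f] for f in feature_ids], dtype=int)
        return ExpressionBlock(list(feature_ids), self.sample_ids, self.values[idx, :], self.block)


@dataclass
class SampleLabels:
    """Binary phenotype per sample; ``y`` holds 1 for positive, 0 for negative."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("labels must align one-to-one with sample ids")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValueError("labels must be 0 (negative) or 1 (positive)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in labels")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def as_mapping(self) -> dict[str, str]:
        return {s: (POSITIVE if v else NEGATIVE) for s, v in zip(self.sample_ids, self.y)}

    def subset(self, sample_ids) -> "SampleLabels":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return SampleLabels(list(sample_ids), self.y[idx])

    def y_for(self, sample_ids) -> np.ndarray:
        return self.subset(sample_ids).y

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")


@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class FilterResult:
    retained: list[str]
    pvalues: dict[str, float]
    alpha: float


@dataclass
class NormalizationStats:
    method: str
    feature_ids: list[str]
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None


# ---------------------------------------------------------------------------
# file I/O


def read_expression(path: str | os.PathLike, block: str = "mRNA") -> ExpressionBlock:
    """Read a tab-delimited expression matrix; rejects malformed input
    with row/column context and negative raw values."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cells = header.split("\t")
        if cells[0] != "feature_id":
            raise FormatError(f"{path}: first header cell must be 'feature_id', got {cells[0]!r}")
        sample_ids = cells[1:]
        if not sample_ids:
            raise FormatError(f"{path}: no sample columns")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cells):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cells)} columns, got {len(parts)}"
                )
            feature_ids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                    ) from None
                if v < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative expression value {v} in column {col}"
                    )
                row.append(v)
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no feature rows")
    return ExpressionBlock(feature_ids, sample_ids, np.array(rows, dtype=float), block)


def write_expression(block: ExpressionBlock, path: str | os.PathLike) -> None:
    if block.n_samples == 0:
        raise ValueError("cannot write a block with no samples")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(block.sample_ids) + "\n")
        for fid, row in zip(block.feature_ids, block.values):
            fh.write(fid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def read_labels(
    path: str | os.PathLike,
    positive_value: str = POSITIVE,
    negative_value: str = NEGATIVE,
) -> SampleLabels:
    sample_ids: list[str] = []
    y: list[int] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "label"]:
            raise FormatError(f"{path}: expected header 'sample_id\\tlabel', got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, lab = parts
            if lab == positive_value:
                y.append(1)
            elif lab == negative_value:
                y.append(0)
            else:
                raise FormatError(
                    f"{path}:{lineno}: label {lab!r} is neither "
                    f"{positive_value!r} nor {negative_value!r}"
                )
            sample_ids.append(sid)
    return SampleLabels(sample_ids, np.array(y))


def write_labels(labels: SampleLabels, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, v in zip(labels.sample_ids, labels.y):
            fh.write(f"{sid}\t{POSITIVE if v else NEGATIVE}\n")


def load_config(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# normalization


def normalization_stats(
    block: ExpressionBlock,
    method: str = "log2_zscore",
    train_samples: list[str] | None = None,
    ddof: int = 0,
) -> NormalizationStats:
    """Fit per-feature normalization statistics on the training samples only.

    ``ddof=0`` is the population-SD convention (default); pass ``ddof=1``
    for the sample-SD convention.
    """
    if method not in NORMALIZATION_METHODS:
        raise ConfigError(f"unknown normalization method {method!r}")
    if method != "log2_zscore":
        return NormalizationStats(method, list(block.feature_ids))
    cols = (
        block.values
        if train_samples is None
        else block.values[:, block.sample_index(train_samples)]
    )
    logged = np.log2(cols + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=ddof)
    return NormalizationStats(method, list(block.feature_ids), mean, sd)


def apply_normalization(block: ExpressionBlock, stats_: NormalizationStats) -> ExpressionBlock:
    if stats_.feature_ids != block.feature_ids:
        raise ValueError("normalization statistics were fitted on a different feature set")
    if stats_.method == "none":
        return ExpressionBlock(block.feature_ids, block.sample_ids, block.values.copy(), block.block)
    logged = np.log2(block.values + 1.0)
    if stats_.method == "log2":
        return ExpressionBlock(block.feature_ids, block.sample_ids, logged, block.block)
    sd = stats_.sd
    safe = np.where(sd > 0, sd, 1.0)  # zero-variance features map to all-zero rows
    z = (logged - stats_.mean[:, None]) / safe[:, None]
    z[sd == 0, :] = 0.0
    return ExpressionBlock(block.feature_ids, block.sample_ids, z, block.block)


def normalize_block(
    block: ExpressionBlock,
    method: str = "log2_zscore",
    train_samples: list[str] | None = None,
    ddof: int = 0,
    return_stats: bool = False,
):
    """Normalize one raw block; z-score statistics come from the training
    samples only and are reapplied to every column."""
    if block.block == "combined":
        raise ValueError("normalize each raw block separately, before combining")
    stats_ = normalization_stats(block, method, train_samples, ddof)
    out = apply_normalization(block, stats_)
    return (out, stats_) if return_stats else out


# ---------------------------------------------------------------------------
# t-test filter


def ttest_filter(
    block: ExpressionBlock,
    labels: SampleLabels,
    alpha: float = 0.05,
    samples: list[str] | None = None,
    equal_var: bool = True,
) -> FilterResult:
    """Per-feature two-sided two-sample t-test between the classes.

    Runs on ``samples`` (typically the training set) when given. Features
    constant in both groups get p = 1 so indices stay stable; retained
    features satisfy p < alpha strictly.
    """
    ids = samples if samples is not None else block.sample_ids
    y = labels.y_for(ids)
    vals = block.values[:, block.sample_index(ids)]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"need >=2 samples per class, got {n_pos} positive / {n_neg} negative")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features are expected and guarded (p = 1 below)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(vals[:, y == 1], vals[:, y == 0], axis=1, equal_var=equal_var)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    retained = [f for f, pv in zip(block.feature_ids, p) if pv < alpha]
    return FilterResult(retained, dict(zip(block.feature_ids, p.astype(float))), alpha)


# ---------------------------------------------------------------------------
# splitting


def split_train_test(
    labels: SampleLabels,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> SplitAssignment:
    """Seeded train/test split; train size is floor(n * fraction).

    The stratified variant allocates floor(n_c * fraction) per class and
    tops up by largest fractional remainder to match the overall size.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError(f"train_fraction must be in (0,1), got {train_fraction}")
    ids = sorted(labels.sample_ids)  # canonical order: input order never affects the split
    n_train = int(np.floor(len(ids) * train_fraction))
    rng = substream(seed, "split")
    if not stratified:
        perm = rng.permutation(len(ids))
        train = [ids[i] for i in perm[:n_train]]
        test = [ids[i] for i in perm[n_train:]]
        y_tr, y_te = labels.y_for(train), labels.y_for(test)
        if len(np.unique(y_tr)) < 2 or (len(test) and len(np.unique(y_te)) < 2):
            warnings.warn("a split part is missing one class; consider stratified=True")
    else:
        by_class: dict[int, list[str]] = {0: [], 1: []}
        ymap = dict(zip(labels.sample_ids, labels.y))
        for s in ids:
            by_class[int(ymap[s])].append(s)
        quota = {c: len(m) * train_fraction for c, m in by_class.items()}
        take = {c: int(np.floor(q)) for c, q in quota.items()}
        leftover = n_train - sum(take.values())
        for c in sorted(quota, key=lambda c: quota[c] - take[c], reverse=True)[:leftover]:
            take[c] += 1
        train, test = [], []
        for c, members in by_class.items():
            perm = rng.permutation(len(members))
            train += [members[i] for i in perm[: take[c]]]
            test += [members[i] for i in perm[take[c] :]]
        train.sort()
        test.sort()
    return SplitAssignment(train, test, seed)


# ---------------------------------------------------------------------------
# block combination


def combine_blocks(blocks: list[ExpressionBlock]) -> ExpressionBlock:
    """Row-concatenate separately normalized blocks over a shared sample set.

    Feature ids are prefixed with their block tag ("mRNA:...") so block
    provenance survives concatenation.
    """
    if not blocks:
        raise ValueError("no blocks to combine")
    ref = blocks[0]
    sample_ids = list(ref.sample_ids)
    ref_set = set(sample_ids)
    parts, fids = [], []
    for b in blocks:
        diff = ref_set.symmetric_difference(b.sample_ids)
        if diff:
            raise ValueError(f"sample sets differ between blocks: {sorted(diff)[:10]}")
        aligned = b.subset_samples(sample_ids) if b.sample_ids != sample_ids else b
        parts.append(aligned.values)
        fids += [f"{b.block}:{f}" for f in b.feature_ids]
    values = np.vstack(parts) if parts else np.empty((0, len(sample_ids)))
    return ExpressionBlock(fids, sample_ids, values, "combined")


def split_combined_ids(feature_ids) -> dict[str, list[str]]:
    """Decompose prefixed combined-feature ids back into per-block ids."""
    out: dict[str, list[str]] = {}
    for fid in feature_ids:
        tag, _, rest = fid.partition(":")
        out.setdefault(tag, []).append(rest)
    return out
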