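"""Patient-disjoint partitioning, scrambling, windowing, puncturing, folds.

The data engineering recreates a patient-wise 10-fold cross-validation
design for RR-interval blocks:

1. ``split_parts`` deals each class's blocks into 10 patient-disjoint parts
   of near-equal block counts.
2. ``scramble`` augments a part's AFL blocks by concatenating several
   permutations of the block order (AFLSC); because the sliding window is
   longer than any single 10 s block, different patient orders yield
   different windows.
3. Each class-per-part sequence is detrended, then ``round_robin_window``
   slides a length-100 window over the circularly extended sequence to
   produce exactly one vector per sample.
4. ``puncture`` removes equidistantly spaced vectors to shrink the AFIB and
   scrambled-AFL vector sets down to the part's NSR count, giving perfectly
   balanced training folds.
5. ``assemble_folds`` builds the 10 train/test fold specifications, one part
   held out for testing per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detrend import DetrendConfig, detrend
from .synthetic import CLASSES, RRBlock

__all__ = ["PartitionPart", "FoldSpec", "split_parts", "scramble",
           "round_robin_window", "puncture", "assemble_folds",
           "class_sequence"]

WINDOW = 100


@dataclass
class PartitionPart:
    """One of the n patient-disjoint parts: per-class block lists."""

    index: int  # 1-based
    blocks_by_class: dict[str, list[RRBlock]] = field(default_factory=dict)

    def rr_count(self, cls: str) -> int:
        return int(sum(b.rr.size for b in self.blocks_by_class.get(cls, [])))

    def patient_ids(self) -> set[str]:
        return {b.patient_id for bs in self.blocks_by_class.values() for b in bs}


@dataclass
class FoldSpec:
    """Train/test vector sets for one cross-validation fold.

    ``train_X``/``test_X`` are (n, window) float arrays; labels are class
    names; ``train_parts`` lists the contributing part indices.
    """

    fold_index: int
    test_part: int
    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray
    train_parts: tuple[int, ...] = ()

    def class_counts(self, split: str = "train") -> dict[str, int]:
        y = self.train_y if split == "train" else self.test_y
        return {c: int(np.sum(y == c)) for c in CLASSES}


def split_parts(blocks: list[RRBlock], n_parts: int = 10,
                seed: int = 0) -> list[PartitionPart]:
    """Deal blocks into patient-disjoint parts, per class, round-robin.

    The per-class patient order is shuffled once with ``seed``; part sizes
    per class differ by at most one block. A class with fewer than
    ``n_parts`` blocks raises a ``ValueError`` naming the class.
    """
    rng = np.random.default_rng(seed)
    parts = [PartitionPart(index=i + 1, blocks_by_class={c: [] for c in CLASSES})
             for i in range(n_parts)]
    for cls in CLASSES:
        cls_blocks = [b for b in blocks if b.label == cls]
        if len(cls_blocks) < n_parts:
            raise ValueError(
                f"class {cls} has {len(cls_blocks)} blocks; need >= {n_parts}")
        order = rng.permutation(len(cls_blocks))
        for pos, j in enumerate(order):
            parts[pos % n_parts].blocks_by_class[cls].append(cls_blocks[j])
    return parts


def scramble(blocks: list[RRBlock], n_perms: int = 3,
             seed: int = 0) -> list[RRBlock]:
    """Concatenate ``n_perms`` uniform permutations of the block order.

    The within-block interval order is preserved; the total RR count scales
    exactly by ``n_perms``. The unscrambled order is not additionally
    included (the identity may occur by chance).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if not blocks:
        raise ValueError("cannot scramble an empty block list")
    rng = np.random.default_rng(seed)
    out: list[RRBlock] = []
    for _ in range(n_perms):
        for j in rng.permutation(len(blocks)):
            out.append(blocks[j])
    return out


def round_robin_window(samples: np.ndarray, window: int = WINDOW) -> np.ndarray:
    """One window per sample over the circularly extended sequence.

    The first ``window`` samples are conceptually copied to the end before
    sliding; equivalently, window *i* is ``samples[(i + j) % len] for j in
    0..window-1``. Returns an (len(samples), window) array.
    """
    samples = np.asarray(samples, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if samples.ndim != 1 or samples.size < 1:
        raise ValueError("samples must be a non-empty 1-D sequence")
    n = samples.size
    idx = (np.arange(n)[:, None] + np.arange(window)[None, :]) % n
    return samples[idx]


def puncture(vectors: np.ndarray, target_count: int) -> np.ndarray:
    """Keep exactly ``target_count`` vectors by removing equidistant ones.

    To remove ``k = N - target`` of ``N`` vectors, the indices
    ``floor(j*N/k)`` for ``j = 0..k-1`` are dropped; kept vectors preserve
    their original order and the gaps between removed indices differ by at
    most one.
    """
    vectors = np.asarray(vectors)
    n = len(vectors)
    if not 1 <= target_count <= n:
        raise ValueError(f"target_count must lie in [1, {n}]")
    k = n - target_count
    if k == 0:
        return vectors
    drop = (np.arange(k) * n) // k
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return vectors[keep]


def class_sequence(part: PartitionPart, cls: str, n_perms: int = 3,
                   seed: int = 0,
                   detrend_cfg: DetrendConfig = DetrendConfig()) -> np.ndarray:
    """Detrended concatenated class sequence for one part.

    AFL is scrambled (``n_perms`` permutations of block order) before
    concatenation; NSR and AFIB keep the natural part order. Detrending is
    applied to the concatenated sequence, before windowing.
    """
    blocks = part.blocks_by_class[cls]
    if cls == "AFL":
        blocks = scramble(blocks, n_perms=n_perms, seed=seed)
    rr = np.concatenate([b.rr for b in blocks])
    return detrend(rr, detrend_cfg)


def assemble_folds(parts: list[PartitionPart], window: int = WINDOW,
                   n_perms: int = 3, seed: int = 0,
                   detrend_cfg: DetrendConfig = DetrendConfig(),
                   ) -> list[FoldSpec]:
    """Build one FoldSpec per part: that part tests, the rest train.

    Per training part, AFIB and scrambled-AFL windows are punctured down to
    the part's NSR window count, so the training classes are exactly
    balanced. Test vectors (NSR, AFIB, scrambled AFL) are unpunctured.
    """
    n_parts = len(parts)
    rng = np.random.default_rng(seed)
    scramble_seeds = {p.index: int(rng.integers(2**31)) for p in parts}

    windows: dict[tuple[int, str], np.ndarray] = {}
    for p in parts:
        for cls in CLASSES:
            if not p.blocks_by_class.get(cls):
                raise ValueError(f"part {p.index} lacks class {cls}")
            seq = class_sequence(p, cls, n_perms=n_perms,
                                 seed=scramble_seeds[p.index],
                                 detrend_cfg=detrend_cfg)
            windows[(p.index, cls)] = round_robin_window(seq, window)

    folds: list[FoldSpec] = []
    for p in parts:
        train_parts = tuple(q.index for q in parts if q.index != p.index)
        tr_X, tr_y = [], []
        for qi in train_parts:
            n_nsr = len(windows[(qi, "NSR")])
            if n_nsr == 0:
                raise ValueError(f"training part {qi} has zero NSR vectors")
            for cls in CLASSES:
                vecs = windows[(qi, cls)]
                if cls != "NSR":
                    if len(vecs) < n_nsr:
                        raise ValueError(
                            f"part {qi}: {cls} has fewer vectors than NSR")
                    vecs = puncture(vecs, n_nsr)
                tr_X.append(vecs)
                tr_y.append(np.full(len(vecs), cls, dtype=object))
        te_X, te_y = [], []
        for cls in CLASSES:
            vecs = windows[(p.index, cls)]
            te_X.append(vecs)
            te_y.append(np.full(len(vecs), cls, dtype=object))
        folds.append(FoldSpec(
            fold_index=p.index, test_part=p.index,
            train_X=np.concatenate(tr_X), train_y=np.concatenate(tr_y),
            test_X=np.concatenate(te_X), test_y=np.concatenate(te_y),
            train_parts=train_parts))
    return folds
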