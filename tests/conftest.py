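"""Shared fixtures and per-base oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ecepi.intervals import GenomicInterval, IntervalSet
from ecepi.simulate import SyntheticDesign, simulate

TOY_CHROM_LEN = 10_000


def random_interval_set(rng: np.random.Generator, n: int = 50,
                        chrom_len: int = TOY_CHROM_LEN,
                        chroms=("toy",)) -> IntervalSet:
    """Random (unsorted, overlapping) intervals on tiny chromosomes."""
    ivs = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        width = int(rng.integers(1, max(2, chrom_len // 20)))
        ivs.append(GenomicInterval(c, start, min(start + width, chrom_len)))
    return IntervalSet(ivs, genome={c: chrom_len for c in chroms})


def coverage_mask(s: IntervalSet, chrom_len: int = TOY_CHROM_LEN) -> dict:
    """Per-base boolean-array oracle representation of an interval set."""
    masks = {}
    for chrom in s.chroms:
        m = np.zeros(chrom_len, dtype=bool)
        for st, en in s.arrays(chrom):
            m[st:en] = True
        masks[chrom] = m
    return masks


def mask_to_intervals(masks: dict, genome=None) -> IntervalSet:
    """Convert per-base boolean arrays back to maximal intervals."""
    data = {}
    for chrom, m in masks.items():
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        if starts.size:
            data[chrom] = np.stack([starts, ends], axis=1)
    return IntervalSet(data, genome=genome)


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared by read-only tests."""
    return simulate(SyntheticDesign(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
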