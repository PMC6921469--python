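"""Permutation test for trait-associated SNP enrichment around enhancer sites.

For every lineage-specific enhancer site a fixed window (default 100 kb,
chosen to absorb linkage disequilibrium) is centred on the site midpoint
and the trait-matched GWAS SNPs inside it are counted.  The null is built
per site by re-placing that site uniformly at random within its own
chromosome — avoiding the centromere and keeping the width — and
recounting; enrichment is reported as Z = (observed - null mean)/null sd
with a default call threshold of Z > 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

DEFAULT_TERMS = ("heart", "coronary", "cardiac")
DEFAULT_WINDOW = 100_000
DEFAULT_Z_THRESHOLD = 5.0


@dataclass
class EnrichmentConfig:
    """Parameters of the permutation enrichment test."""

    terms: Tuple[str, ...] = DEFAULT_TERMS
    window: int = DEFAULT_WINDOW
    n_perm: int = 1000
    z_threshold: float = DEFAULT_Z_THRESHOLD
    seed: int = 0
    centromeres: Optional[IntervalSet] = None

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def read_snp_catalog(path: str) -> pd.DataFrame:
    """Read a SNP catalog TSV with columns chrom, pos, trait."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait": str})
    missing = {"chrom", "pos", "trait"} - set(df.columns)
    if missing:
        raise ValueError(f"SNP catalog missing columns: {sorted(missing)}")
    return df


def match_snps(catalog: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """SNPs whose trait string contains any term (case-insensitive substring).

    The result is de-duplicated by (chrom, pos): a SNP listed once per
    associated trait counts once.
    """
    if not terms:
        raise ValueError("term list must not be empty")
    low = catalog["trait"].str.lower()
    mask = np.zeros(len(catalog), dtype=bool)
    for t in terms:
        mask |= low.str.contains(t.lower(), regex=False).to_numpy()
    return (catalog[mask]
            .drop_duplicates(subset=["chrom", "pos"])
            .reset_index(drop=True))


def _snp_positions(snps: pd.DataFrame) -> Dict[str, np.ndarray]:
    return {str(c): np.sort(g["pos"].to_numpy(dtype=np.int64))
            for c, g in snps.groupby("chrom")}


def _count_in_windows(mids: np.ndarray, pos: np.ndarray, window: int,
                      chrom_len: Optional[int]) -> np.ndarray:
    """SNPs with position in [mid - window//2, mid + window//2), window
    clipped at the chromosome ends."""
    half = window // 2
    lo = np.maximum(mids - half, 0)
    hi = mids + (window - half)
    if chrom_len is not None:
        hi = np.minimum(hi, chrom_len)
    return (np.searchsorted(pos, hi, side="left")
            - np.searchsorted(pos, lo, side="left"))


def observed_counts(sites: pd.DataFrame, snps: pd.DataFrame, window: int = DEFAULT_WINDOW,
                    genome: Optional[Mapping[str, int]] = None) -> pd.Series:
    """Matched-SNP count in the window centred on each site midpoint."""
    widths = sites["end"] - sites["start"]
    if (window < widths).any():
        logger.warning("window (%d bp) narrower than %d site(s)", window,
                       int((window < widths).sum()))
    pos_by_chrom = _snp_positions(snps)
    out = pd.Series(0, index=pd.Index(sites["site_id"], name="site_id"), dtype=int)
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = pos_by_chrom.get(str(chrom), np.empty(0, dtype=np.int64))
        mids = ((grp["start"] + grp["end"]) // 2).to_numpy(dtype=np.int64)
        L = genome.get(str(chrom)) if genome else None
        out.loc[grp["site_id"].to_numpy()] = _count_in_windows(mids, pos, window, L)
    return out


def _allowed_draws(rng: np.random.Generator, n: int, width: int, chrom_len: int,
                   cent: np.ndarray) -> np.ndarray:
    """Rejection-sample n start positions on [0, L-width] whose site
    [s, s+width) misses every centromeric interval."""
    max_start = chrom_len - width
    if max_start < 0:
        raise ValueError(f"site of width {width} does not fit on chromosome "
                         f"of length {chrom_len}")
    out = np.empty(n, dtype=np.int64)
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise ValueError("no centromere-free placement found for site "
                             f"of width {width} (chromosome length {chrom_len})")
        draw = rng.integers(0, max_start + 1, size=max(n - filled, 64))
        ok = np.ones(draw.size, dtype=bool)
        for cs, ce in cent:
            ok &= (draw + width <= cs) | (draw >= ce)
        good = draw[ok][: n - filled]
        out[filled:filled + good.size] = good
        filled += good.size
    return out


def permute_sites(sites: pd.DataFrame, genome: Mapping[str, int],
                  centromeres: Optional[IntervalSet], seed: int) -> pd.DataFrame:
    """One within-chromosome random re-placement of every site.

    Widths and chromosomes are preserved; placements avoid centromeric
    intervals; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in sites.itertuples(index=False):
        width = int(row.end - row.start)
        cent = (centromeres.arrays(str(row.chrom)) if centromeres is not None
                else np.empty((0, 2), dtype=np.int64))
        start = int(_allowed_draws(rng, 1, width, int(genome[str(row.chrom)]), cent)[0])
        rows.append((row.site_id, row.chrom, start, start + width))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "start", "end"])


def enrichment_z(sites: pd.DataFrame, snps: pd.DataFrame, cfg: EnrichmentConfig,
                 genome: Mapping[str, int]) -> pd.DataFrame:
    """Per-site permutation Z-scores for matched-SNP enrichment.

    The null for each site is the distribution of window counts at
    ``cfg.n_perm`` random placements of that same site on its own
    chromosome.  Sites whose null count never varies (sd = 0) get a
    missing Z and are never called enriched.
    """
    matched = match_snps(snps, cfg.terms)
    pos_by_chrom = _snp_positions(matched)
    obs = observed_counts(sites, matched, cfg.window, genome)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for row in sites.itertuples(index=False):
        chrom = str(row.chrom)
        width = int(row.end - row.start)
        L = int(genome[chrom])
        cent = (cfg.centromeres.arrays(chrom) if cfg.centromeres is not None
                else np.empty((0, 2), dtype=np.int64))
        starts = _allowed_draws(rng, cfg.n_perm, width, L, cent)
        mids = starts + width // 2
        pos = pos_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        null = _count_in_windows(mids, pos, cfg.window, L)
        mu = float(null.mean())
        sd = float(null.std(ddof=0))
        o = int(obs[row.site_id])
        if sd == 0.0:
            logger.info("site %s: degenerate null (sd = 0), Z undefined", row.site_id)
            z, enriched = np.nan, False
        else:
            z = (o - mu) / sd
            enriched = z > cfg.z_threshold
        rows.append((row.site_id, o, mu, sd, z, enriched))
    return pd.DataFrame(
        rows, columns=["site_id", "observed", "null_mean", "null_sd", "z", "enriched"]
    ).set_index("site_id")
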