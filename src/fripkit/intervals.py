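"""Interval-based FRiP: reads-in-peaks fractions from BED-style intervals.

Intervals are pandas DataFrames with ``chrom``, ``start``, ``end`` columns in
BED convention (0-based, half-open). FRiP counts a read as in-peak when it
shares at least one basepair with the flattened (coverage-union) peak set;
book-ended intervals merge during flattening. An optional exclusion set
(e.g. a blacklist) removes reads from both numerator and denominator. The
genome fraction covered by peaks, rho, is the expected in-peak rate of
uniformly distributed background reads.
"""

from __future__ import annotations

from statistics import median
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BedParseError",
    "intervals_df",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "flatten",
    "total_bp",
    "overlaps_any",
    "frip",
    "peak_genome_fraction",
    "frip_ratio",
]

_CORE = ["chrom", "start", "end"]
_NARROWPEAK_EXTRAS = ["name", "score", "strand", "signalValue", "pValue",
                      "qValue", "peak"]


class BedParseError(ValueError):
    """Malformed BED input; the message names the offending line."""


def intervals_df(records: Iterable[tuple]) -> pd.DataFrame:
    """Build an interval frame from (chrom, start, end[, ...]) tuples."""
    rows = list(records)
    ncol = max((len(r) for r in rows), default=3)
    cols = _CORE + [f"col{i}" for i in range(4, ncol + 1)]
    df = pd.DataFrame(rows, columns=cols[:ncol]) if rows else pd.DataFrame(
        columns=_CORE
    )
    return _validated(df)


def _validated(df: pd.DataFrame, path=None) -> pd.DataFrame:
    if len(df):
        df = df.astype({"start": np.int64, "end": np.int64})
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            line = int(bad[0]) + 1
            where = f"{path}, line {line}" if path else f"record {line}"
            raise BedParseError(f"start >= end at {where}")
        if (df["start"] < 0).any():
            raise BedParseError("negative start coordinate")
    return df.reset_index(drop=True)


def read_bed(path) -> pd.DataFrame:
    """Read BED3+/narrowPeak. Extra columns are preserved; a 10-column file
    gets narrowPeak column names. Raises :class:`BedParseError` with the line
    number on malformed input."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            skip_blank_lines=True, dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_CORE)
    except ValueError as exc:
        raise BedParseError(f"cannot parse {path}: {exc}") from exc
    # drop UCSC track/browser lines if present
    mask = df[0].astype(str).str.match(r"^(track|browser)\b")
    df = df[~mask]
    if df.shape[1] < 3:
        raise BedParseError(f"{path}: fewer than 3 columns")
    ncol = df.shape[1]
    if ncol == 10:
        df.columns = _CORE + _NARROWPEAK_EXTRAS
    else:
        df.columns = _CORE + [f"col{i}" for i in range(4, ncol + 1)]
    for col in ("start", "end"):
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError as exc:
            raise BedParseError(f"{path}: non-integer {col}: {exc}") from exc
    return _validated(df, path)


def write_bed(df: pd.DataFrame, path, extras: bool = False) -> None:
    """Write BED; only chrom/start/end unless ``extras`` keeps the rest."""
    cols = list(df.columns) if extras else _CORE
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom<TAB>length table (UCSC chrom.sizes dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    sizes = dict(zip(df["chrom"], df["length"].astype(int)))
    if any(v <= 0 for v in sizes.values()):
        raise ValueError("chromosome lengths must be positive")
    return sizes


def write_chrom_sizes(genome: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(genome), "length": list(genome.values())}
    ).to_csv(path, sep="\t", header=False, index=False)


def flatten(df: pd.DataFrame) -> pd.DataFrame:
    """Coverage union: disjoint sorted intervals covering the same basepairs.

    Book-ended intervals ([0,10) + [10,20)) merge; total bp is preserved for
    already-disjoint input.
    """
    if not len(df):
        return pd.DataFrame(columns=_CORE)
    pieces = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        run_end = np.maximum.accumulate(ends)
        # new block whenever a start exceeds the running max end so far
        new_block = np.ones(len(sub), dtype=bool)
        new_block[1:] = starts[1:] > run_end[:-1]
        block = np.cumsum(new_block) - 1
        out_starts = starts[new_block]
        out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
        pieces.append(
            pd.DataFrame({"chrom": chrom, "start": out_starts, "end": out_ends})
        )
    return pd.concat(pieces, ignore_index=True)


def total_bp(df: pd.DataFrame) -> int:
    """Basepairs covered (input flattened first)."""
    flat = flatten(df)
    if not len(flat):
        return 0
    return int((flat["end"] - flat["start"]).sum())


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: shares >= 1 bp with the subject's coverage union.

    The subject is flattened, then each query interval [a, b) is tested
    against the unique candidate merged interval with the largest start < b.
    """
    query = query.reset_index(drop=True)
    flat = flatten(subject)
    out = np.zeros(len(query), dtype=bool)
    if not len(flat) or not len(query):
        return out
    by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in flat.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        s, e = by_chrom[chrom]
        a = sub["start"].to_numpy()
        b = sub["end"].to_numpy()
        idx = np.searchsorted(s, b, side="left") - 1
        hit = (idx >= 0) & (e[np.clip(idx, 0, None)] > a)
        out[sub.index.to_numpy()] = hit
    return out


def frip(
    reads: pd.DataFrame,
    peaks: pd.DataFrame,
    exclude: pd.DataFrame | None = None,
) -> float:
    """Fraction of reads overlapping the flattened peak set by >= 1 bp.

    Reads overlapping ``exclude`` are removed from numerator and denominator
    before counting. Raises if no reads remain.
    """
    reads = reads.reset_index(drop=True)
    if exclude is not None and len(exclude):
        keep = ~overlaps_any(reads, exclude)
        reads = reads[keep].reset_index(drop=True)
    if not len(reads):
        raise ValueError("no reads retained after exclusion")
    hits = overlaps_any(reads, peaks)
    return float(hits.sum()) / len(reads)


def peak_genome_fraction(peaks: pd.DataFrame, genome: Mapping[str, int]) -> float:
    """rho: flattened peak basepairs over total genome basepairs."""
    genome_bp = sum(genome.values())
    if genome_bp <= 0:
        raise ValueError("genome has no basepairs")
    if len(peaks):
        for chrom, sub in peaks.groupby("chrom"):
            if chrom not in genome:
                raise ValueError(f"peak chromosome {chrom!r} not in genome table")
            if int(sub["end"].max()) > genome[chrom]:
                raise ValueError(f"peak beyond end of {chrom}")
    return total_bp(peaks) / genome_bp


def frip_ratio(frip_perturbed: float, frip_unperturbed) -> float:
    """Perturbed-over-unperturbed FRiP; a collection of unperturbed values is
    reduced to its median first."""
    if np.ndim(frip_unperturbed) > 0:
        ref = float(median(list(frip_unperturbed)))
    else:
        ref = float(frip_unperturbed)
    if ref <= 0:
        raise ValueError("unperturbed FRiP must be positive")
    return float(frip_perturbed) / ref
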