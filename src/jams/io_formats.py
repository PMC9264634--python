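"""Readers and writers for the external file formats the pipeline touches.

All internal coordinates are 0-based, half-open.  Formats that use other
conventions (bismark coverage files are 1-based) are converted at the
boundary, on read, and converted back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "PeakRecord",
    "CpGTable",
    "SignalTrack",
    "PFM",
    "read_genome",
    "read_peaks",
    "read_narrowpeak",
    "write_peaks",
    "read_cpg_coverage",
    "write_cpg_coverage",
    "read_bedgraph",
    "write_bedgraph",
    "read_pfm",
    "read_bed_intervals",
]

_VALID_BASES = set("ACGTN")


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase DNA string.

    Lookups use 0-based half-open intervals and always return a string of
    exactly the requested length, or raise.
    """

    def __init__(self, chroms: dict[str, str]):
        self._chroms = {}
        for name, seq in chroms.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._chroms[name] = seq

    def chroms(self) -> list[str]:
        return list(self._chroms)

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak: summit plus pulldown/control read counts."""

    chrom: str
    summit: int  # 0-based
    pulldown_count: int
    control_count: int
    peak_id: str

    def __post_init__(self):
        if self.summit < 0:
            raise ValueError(f"peak {self.peak_id}: negative summit")
        if self.pulldown_count < 0 or self.control_count < 0:
            raise ValueError(f"peak {self.peak_id}: negative count")


class CpGTable:
    """Per-CpG methylated/unmethylated read counts.

    Positions are the 0-based coordinate of the cytosine on the strand the
    call was made on.  ``fraction`` is recomputed from counts; a site with
    zero coverage has an undefined (NaN) fraction but is retained.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "pos", "meth", "unmeth"}
        if not required <= set(frame.columns):
            raise ValueError(f"CpGTable requires columns {sorted(required)}")
        if (frame[["meth", "unmeth"]] < 0).to_numpy().any():
            raise ValueError("negative methylation counts")
        if frame.duplicated(["chrom", "pos"]).any():
            dup = frame[frame.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicated CpG position {dup['chrom']}:{dup['pos']}")
        self.frame = frame.reset_index(drop=True)
        # position -> row lookup per chromosome for O(1) retrieval
        self._index: dict[str, dict[int, int]] = {}
        for i, (chrom, pos) in enumerate(
            zip(frame["chrom"].to_numpy(), frame["pos"].to_numpy())
        ):
            self._index.setdefault(chrom, {})[int(pos)] = i

    def __len__(self) -> int:
        return len(self.frame)

    def counts_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """(meth, unmeth) at a site, (0, 0) if the site is absent."""
        row = self._index.get(chrom, {}).get(pos)
        if row is None:
            return (0, 0)
        rec = self.frame.iloc[row]
        return (int(rec["meth"]), int(rec["unmeth"]))

    def fraction_at(self, chrom: str, pos: int) -> float:
        meth, unmeth = self.counts_at(chrom, pos)
        cov = meth + unmeth
        return meth / cov if cov > 0 else float("nan")


class SignalTrack:
    """Sparse non-negative signal: sorted non-overlapping intervals per chrom.

    ``mean(chrom, start, end)`` is the length-weighted average over covered
    bases; uncovered bases contribute signal 0 with full weight, and a query
    entirely outside coverage returns 0.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_lists(cls, records: list[tuple[str, int, int, float]]) -> "SignalTrack":
        per_chrom: dict[str, list] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        return cls(
            {
                c: (
                    np.array([r[0] for r in rows]),
                    np.array([r[1] for r in rows]),
                    np.array([r[2] for r in rows]),
                )
                for c, rows in per_chrom.items()
            }
        )

    def chroms(self) -> list[str]:
        return list(self._data)

    def records(self):
        for chrom, (starts, ends, values) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        total = float(np.sum(ov * values[lo:hi]))
        return total / (end - start)


class PFM:
    """Position frequency matrix: L x 4 probabilities over (A, C, G, T)."""

    BASES = "ACGT"

    def __init__(self, matrix: np.ndarray, name: str = "motif"):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("PFM must be an L x 4 matrix")
        if matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(matrix < 0):
            raise ValueError("PFM entries must be non-negative")
        sums = matrix.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("PFM row sums to zero")
        self.matrix = matrix / sums[:, None]
        self.name = name

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(self.BASES[i] for i in np.argmax(self.matrix, axis=1))


def read_genome(path) -> GenomeSequence:
    """Read a FASTA file into a GenomeSequence (sequences uppercased)."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        chroms[record.id] = str(record.seq)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chroms)


def read_peaks(path) -> list[PeakRecord]:
    """Read a tab-delimited peak table.

    Expected header columns: chrom, summit (0-based), pulldown, control, and
    optionally peak_id.  Row order is preserved.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "summit", "pulldown", "control"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    peaks = []
    for i, row in frame.iterrows():
        for col in ("summit", "pulldown", "control"):
            value = row[col]
            if float(value) != int(value):
                raise ValueError(f"row {i}: non-integer {col} value {value!r}")
            if int(value) < 0:
                raise ValueError(f"row {i}: negative {col} value {value!r}")
        peak_id = str(row["peak_id"]) if "peak_id" in frame.columns else f"peak_{i}"
        peaks.append(
            PeakRecord(
                chrom=str(row["chrom"]),
                summit=int(row["summit"]),
                pulldown_count=int(row["pulldown"]),
                control_count=int(row["control"]),
                peak_id=peak_id,
            )
        )
    return peaks


def read_narrowpeak(peak_path, counts_path) -> list[PeakRecord]:
    """Read peaks from narrowPeak plus a separate count table.

    narrowPeak is 0-based BED6+4; the summit is ``start + offset`` using
    the 10th column.  ``counts_path`` is tab-delimited with columns
    peak_id (matching the narrowPeak name column), pulldown, control.
    """
    np_cols = [
        "chrom", "start", "end", "name", "score",
        "strand", "signal", "p", "q", "offset",
    ]
    frame = pd.read_csv(
        peak_path, sep="\t", header=None, names=np_cols, dtype={"chrom": str}
    )
    counts = pd.read_csv(counts_path, sep="\t", dtype={"peak_id": str})
    required = {"peak_id", "pulldown", "control"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table requires columns {sorted(required)}")
    counts = counts.set_index("peak_id")
    peaks = []
    for i, row in frame.iterrows():
        name = str(row["name"])
        if name not in counts.index:
            raise ValueError(f"row {i}: no counts for peak {name!r}")
        offset = int(row["offset"])
        if offset < 0:
            raise ValueError(f"row {i}: negative summit offset")
        rec = counts.loc[name]
        peaks.append(
            PeakRecord(
                chrom=str(row["chrom"]),
                summit=int(row["start"]) + offset,
                pulldown_count=int(rec["pulldown"]),
                control_count=int(rec["control"]),
                peak_id=name,
            )
        )
    return peaks


def write_peaks(peaks: list[PeakRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "summit": [p.summit for p in peaks],
            "pulldown": [p.pulldown_count for p in peaks],
            "control": [p.control_count for p in peaks],
            "peak_id": [p.peak_id for p in peaks],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_cpg_coverage(path) -> CpGTable:
    """Read a bismark-style coverage file.

    Columns: chrom, start (1-based), end, methylation %, count_methylated,
    count_unmethylated.  Positions are converted to 0-based; the printed
    percentage is never trusted — the fraction is recomputed from counts
    (with a warning when the two disagree by more than one percentage
    point).
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    cov = frame["meth"] + frame["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        recomputed = 100.0 * frame["meth"] / cov
    mismatch = (cov > 0) & (np.abs(recomputed - frame["pct"]) > 1.0)
    if mismatch.any():
        i = int(np.flatnonzero(mismatch.to_numpy())[0])
        warnings.warn(
            f"{int(mismatch.sum())} site(s) have a methylation % inconsistent "
            f"with their counts (first at row {i}); counts win",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": frame["start"].astype(np.int64) - 1,  # bismark is 1-based
            "meth": frame["meth"].astype(np.int64),
            "unmeth": frame["unmeth"].astype(np.int64),
        }
    )
    return CpGTable(out)


def write_cpg_coverage(table: CpGTable, path) -> None:
    """Write a CpGTable back to bismark coverage format (1-based)."""
    frame = table.frame
    cov = (frame["meth"] + frame["unmeth"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * frame["meth"].to_numpy() / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["pos"] + 1,
            "end": frame["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": frame["meth"],
            "unmeth": frame["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> SignalTrack:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        comment="#",
    )
    return SignalTrack.from_lists(
        list(
            zip(
                frame["chrom"],
                frame["start"].astype(int),
                frame["end"].astype(int),
                frame["value"].astype(float),
            )
        )
    )


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.12g}\n")


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file of intervals (e.g. a repeat mask)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for chrom in out:
        out[chrom].sort()
    return out


def read_pfm(path) -> PFM:
    """Read a motif as a whitespace-delimited L x 4 matrix or MEME minimal format.

    Rows are renormalized to sum to 1 (count matrices are accepted).
    """
    with open(path) as fh:
        text = fh.read()
    if "MEME version" in text:
        return _read_meme_minimal(text)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", ">")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(
                f"line {lineno}: expected 4 columns (A C G T), got {len(fields)}"
            )
        rows.append([float(x) for x in fields])
    if not rows:
        raise ValueError("no matrix rows found")
    return PFM(np.array(rows))


def _read_meme_minimal(text: str) -> PFM:
    lines = iter(text.splitlines())
    name = "motif"
    rows: list[list[float]] = []
    in_matrix = False
    for line in lines:
        line = line.strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else name
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix:
            if not line:
                break
            fields = line.split()
            if len(fields) != 4:
                break
            rows.append([float(x) for x in fields])
    if not rows:
        raise ValueError("no letter-probability matrix found in MEME input")
    return PFM(np.array(rows), name=name)
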