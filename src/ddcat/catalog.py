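"""Mutation catalogs, opportunity counting and opportunity renormalization.

Coordinate conventions: mutation tables are 1-based (ICGC/VCF style); BED
region files are 0-based half-open.  Genomes may be either a
``pyfaidx.Fasta`` handle or a plain mapping of chromosome name to sequence
string (the synthetic generator produces the latter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import (BASES, COMPLEMENT, Categorization, UNIVERSE_SIZE,
                       encode_sequence)

DEFAULT_COLUMNS = ("sample_id", "chromosome", "position",
                   "reference_allele", "mutated_allele")

_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def _chrom_string(genome, chrom: str) -> str:
    seq = genome[chrom]
    return str(seq[:]) if not isinstance(seq, str) else seq


def _chrom_names(genome) -> list[str]:
    return list(genome.keys())


class ExtractionError(ValueError):
    """A mutation record that cannot yield a valid 7-mer mutation sequence."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


def extract_mutation_sequence(genome, chrom: str, pos: int,
                              ref: str, alt: str) -> str:
    """Extract the pyrimidine-collapsed 8-character mutation sequence.

    ``pos`` is 1-based.  When the reference base is a purine the 7-mer
    window is reverse-complemented and the alternative base complemented,
    so position 4 of the result is always C or T.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ExtractionError("non_snv", f"not a single-base substitution: {ref}>{alt}")
    chrom_seq = genome[chrom]
    start, end = pos - 4, pos + 3          # 0-based half-open +-3 window
    if start < 0:
        raise ExtractionError("out_of_bounds", f"{chrom}:{pos} window out of bounds")
    window = str(chrom_seq[start:end]).upper()
    if len(window) != 7:
        raise ExtractionError("out_of_bounds", f"{chrom}:{pos} window out of bounds")
    if any(b not in BASES for b in window):
        raise ExtractionError("ambiguous_base", f"{chrom}:{pos} window contains N")
    if window[3] != ref:
        raise ExtractionError(
            "reference_mismatch",
            f"{chrom}:{pos} genome has {window[3]}, record says {ref}")
    if ref in "AG":
        window = "".join(COMPLEMENT[b] for b in reversed(window))
        alt = COMPLEMENT[alt]
    return window[:4] + alt + window[4:]


@dataclass
class CohortSequences:
    """Per-record mutation-sequence indices for a cohort.

    Extraction is independent of any categorization, so it is done once per
    cohort; catalogs under a categorization are then a table lookup.
    """

    sample_ids: list[str]
    sample_index: np.ndarray        # (R,) int32 per usable record
    seq_index: np.ndarray           # (R,) int32 universe index per record
    rejections: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def extract_cohort(genome, records: pd.DataFrame,
                   sample_order: list[str] | None = None,
                   deduplicate: bool = False) -> CohortSequences:
    """Extract sequence indices for every usable record of a mutation table.

    Rejected records (reference mismatch, N in window, window out of
    bounds, non-SNV alleles) are tallied by reason, never fatal.
    """
    req = set(DEFAULT_COLUMNS)
    if not req.issubset(records.columns):
        raise ValueError(f"mutation table must have columns {sorted(req)}")
    if deduplicate:
        records = records.drop_duplicates(subset=list(DEFAULT_COLUMNS))
    samples = (sample_order if sample_order is not None
               else sorted(records["sample_id"].unique()))
    sample_pos = {s: i for i, s in enumerate(samples)}
    chrom_cache: dict[str, str] = {}
    known = set(_chrom_names(genome))
    sidx, qidx = [], []
    rejections: dict[str, int] = {}
    for row in records.itertuples(index=False):
        rec = row._asdict()
        chrom = str(rec["chromosome"])
        if chrom not in known:
            rejections["unknown_chromosome"] = rejections.get("unknown_chromosome", 0) + 1
            continue
        if chrom not in chrom_cache:
            chrom_cache[chrom] = _chrom_string(genome, chrom)
        try:
            seq = extract_mutation_sequence(
                chrom_cache, chrom, int(rec["position"]),
                str(rec["reference_allele"]), str(rec["mutated_allele"]))
        except ExtractionError as e:
            rejections[e.reason] = rejections.get(e.reason, 0) + 1
            continue
        sid = rec["sample_id"]
        if sid not in sample_pos:
            rejections["unknown_sample"] = rejections.get("unknown_sample", 0) + 1
            continue
        sidx.append(sample_pos[sid])
        qidx.append(encode_sequence(seq))
    return CohortSequences(
        sample_ids=list(samples),
        sample_index=np.asarray(sidx, dtype=np.int32),
        seq_index=np.asarray(qidx, dtype=np.int32),
        rejections=rejections)


@dataclass
class MutationCatalog:
    """Samples x categories mutation count matrix."""

    counts: np.ndarray              # (N, M) int64
    sample_ids: list[str]
    category_labels: list[str]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.category_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def build_catalog(cohort: CohortSequences, cat: Categorization,
                  provenance: dict | None = None) -> MutationCatalog:
    """Bin a cohort's mutation sequences into a categorization's categories."""
    if cohort.seq_index.size == 0:
        raise ValueError("no usable mutation records")
    table = cat.assignment
    m = cat.n_categories
    n = cohort.n_samples
    flat = cohort.sample_index.astype(np.int64) * m + table[cohort.seq_index]
    counts = np.bincount(flat, minlength=n * m).reshape(n, m)
    return MutationCatalog(counts=counts, sample_ids=list(cohort.sample_ids),
                           category_labels=cat.category_labels(),
                           provenance={"categorization": cat.name,
                                       **(provenance or {})})


def normalize_rows(catalog: MutationCatalog | np.ndarray) -> np.ndarray:
    """Row-normalize a count matrix to per-sample category proportions."""
    counts = catalog.counts if isinstance(catalog, MutationCatalog) else catalog
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = np.nonzero(totals == 0)[0]
        ids = (np.array(catalog.sample_ids)[bad].tolist()
               if isinstance(catalog, MutationCatalog) else bad.tolist())
        raise ValueError(f"samples with zero mutations: {ids}")
    return counts / totals[:, None]


# ---------------------------------------------------------------------------
# Mutation opportunities
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return df


def _region_mask(length: int, intervals: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for row in intervals.itertuples(index=False):
        mask[max(0, int(row.start)):min(length, int(row.end))] = True
    return mask


def opportunity_sequence_indices(genome, regions: pd.DataFrame | None = None
                                 ) -> np.ndarray:
    """Universe indices of all (position, alt) mutation opportunities.

    Every genomic position whose full 7-mer window is N-free (and, when
    ``regions`` is given, whose central base lies inside a region)
    contributes three pyrimidine-collapsed sequences, one per alternative
    base.
    """
    chunks = []
    for chrom in _chrom_names(genome):
        s = _chrom_string(genome, chrom)
        codes = _CODE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]
        if codes.size < 7:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, 7)
        ok = (win >= 0).all(axis=1)
        if regions is not None:
            sub = regions[regions["chrom"] == chrom]
            mask = _region_mask(codes.size, sub)
            ok &= mask[3:codes.size - 3]
        w = win[ok].astype(np.int64)
        if w.shape[0] == 0:
            continue
        purine = (w[:, 3] == 0) | (w[:, 3] == 2)
        w[purine] = 3 - w[purine][:, ::-1]
        fl = w[:, 0] * 16 + w[:, 1] * 4 + w[:, 2]
        fr = w[:, 4] * 16 + w[:, 5] * 4 + w[:, 6]
        ref_bit = (w[:, 3] == 3).astype(np.int64)
        base = ((fl * 2 + ref_bit) * 3) * 64 + fr
        idx = base[:, None] + np.arange(3, dtype=np.int64)[None, :] * 64
        chunks.append(idx.ravel())
    if not chunks:
        raise ValueError("no eligible positions (genome empty or all N)")
    out = np.concatenate(chunks).astype(np.int32)
    assert out.max() < UNIVERSE_SIZE
    return out


@dataclass
class OpportunityVector:
    """Per-category counts of (position, alt) mutation opportunities."""

    u: np.ndarray               # (M,) int64
    region: str = "genome"
    n_positions: int = 0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.int64)


def count_opportunities(genome, cat: Categorization,
                        regions: pd.DataFrame | None = None,
                        region_label: str | None = None) -> OpportunityVector:
    """Count per-category mutation opportunities in a genome or region set."""
    idx = opportunity_sequence_indices(genome, regions)
    table = cat.assignment
    u = np.bincount(table[idx], minlength=cat.n_categories)
    label = region_label or ("exome" if regions is not None else "genome")
    return OpportunityVector(u=u, region=label, n_positions=idx.size // 3)


def renormalize_signatures(h: np.ndarray, u_src, u_dst) -> np.ndarray:
    """Rescale signature rows from one opportunity regime to another.

    Each row is multiplied elementwise by ``u_dst / u_src`` and renormalized
    to sum to 1.  Categories unobservable in the source regime (u_src = 0)
    get ratio 0, with a warning when signature mass would be lost there.
    """
    u_src = u_src.u if isinstance(u_src, OpportunityVector) else np.asarray(u_src, float)
    u_dst = u_dst.u if isinstance(u_dst, OpportunityVector) else np.asarray(u_dst, float)
    h = np.asarray(h, dtype=float)
    ratio = np.zeros_like(u_src, dtype=float)
    nz = u_src > 0
    ratio[nz] = u_dst[nz] / u_src[nz]
    lost = (~nz) & (u_dst > 0) & (h.sum(axis=0) > 0)
    if np.any(lost):
        warnings.warn(f"{int(lost.sum())} categories unobservable in the "
                      "source regime carry signature mass; ratio set to 0")
    scaled = h * ratio[None, :]
    totals = scaled.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a signature lost all mass during renormalization")
    return scaled / totals[:, None]


def read_mutation_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an ICGC-style simple somatic mutation TSV.

    ``column_map`` maps the file's column names onto the canonical
    (sample_id, chromosome, position, reference_allele, mutated_allele).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(DEFAULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    df["chromosome"] = df["chromosome"].astype(str)
    return df
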