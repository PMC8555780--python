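"""Self-contained synthetic fixtures: genome + exome, mutation cohorts with
planted context-specific signatures, and expression matrices coupled to the
planted exposures.

Everything is generated programmatically and bit-reproducible under a
seed.  Mutations are placed at real positions of the synthetic genome so
the FASTA round-trip, pyrimidine collapsing and opportunity machinery are
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (CohortSequences, extract_cohort,
                      opportunity_sequence_indices, _CODE_LUT)
from .fitness import DatasetBundle, cca_test_correlation
from .ga import resolve_conflicts, sample_category
from .patterns import (BASES, COMPLEMENT, CategoryPattern, Categorization,
                       JOKER_TEXT, UNIVERSE_SIZE, _match_matrix,
                       parse_pattern, universe)

# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    chroms: dict                        # name -> sequence string
    exome: pd.DataFrame                 # BED-style chrom/start/end (0-based)

    def keys(self):
        return self.chroms.keys()

    def __getitem__(self, chrom):
        return self.chroms[chrom]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_bed(self, path) -> None:
        self.exome.to_csv(path, sep="\t", header=False, index=False)


def simulate_genome(length: int = 200_000, gc_content: float = 0.4,
                    exome_fraction: float = 0.25, exon_length: int = 150,
                    n_chroms: int = 1, seed: int = 0) -> SyntheticGenome:
    """I.i.d. random genome with a disjoint random "exome" interval set."""
    if length < 1000:
        raise ValueError("length must be at least 1000")
    if not 0 < exome_fraction <= 1:
        raise ValueError("exome fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    chroms, beds = {}, []
    per_chrom = length // n_chroms
    for c in range(n_chroms):
        name = f"chr{c + 1}"
        codes = rng.choice(4, size=per_chrom, p=p)
        chroms[name] = "".join(BASES[i] for i in codes)
        n_exons = max(1, int(per_chrom * exome_fraction / exon_length))
        slack = per_chrom - n_exons * exon_length
        gaps = rng.multinomial(slack, np.ones(n_exons + 1) / (n_exons + 1))
        start = 0
        for i in range(n_exons):
            start += gaps[i]
            beds.append((name, start, start + exon_length))
            start += exon_length
    exome = pd.DataFrame(beds, columns=["chrom", "start", "end"])
    return SyntheticGenome(chroms=chroms, exome=exome)


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    h_true_seq: np.ndarray              # (K, 24576) distributions over sequences
    generating_patterns: list           # per-signature lists of pattern text
    planted_categorization: Categorization
    seed: int


def simulate_truth(k_true: int = 3, patterns_per_signature: int = 4,
                   within_pattern_mass: float = 0.9, seed: int = 0,
                   concentration: float = 10.0) -> SyntheticTruth:
    """Plant ``k_true`` signatures with context structure up to 3 bases out.

    Each signature spreads ``within_pattern_mass`` of its probability
    uniformly over the sequences matching its generating degenerate
    patterns and the remainder uniformly over the rest of the universe.
    The generating patterns are also embedded in a planted categorization
    (filled to 96 with sampled categories plus the joker).
    """
    if k_true < 1:
        raise ValueError("k_true must be at least 1")
    rng = np.random.default_rng(seed)
    h = np.empty((k_true, UNIVERSE_SIZE))
    gen_patterns: list[list[str]] = []
    all_pats: list[CategoryPattern] = []
    for k in range(k_true):
        pats = [sample_category(concentration, rng)
                for _ in range(patterns_per_signature)]
        mask = _match_matrix(pats).any(axis=0)
        if not mask.any():
            raise ValueError("generating patterns cover no sequences")
        row = np.where(mask, within_pattern_mass / mask.sum(), 0.0)
        if mask.sum() < UNIVERSE_SIZE:
            row[~mask] = (1 - within_pattern_mass) / (~mask).sum()
        h[k] = row / row.sum()
        gen_patterns.append([p.text for p in pats])
        all_pats.extend(pats)
    fill = [sample_category(concentration, rng)
            for _ in range(95 - len(all_pats))]
    planted = resolve_conflicts(all_pats + fill + [parse_pattern(JOKER_TEXT)],
                                rng, concentration)
    planted.name = "planted"
    return SyntheticTruth(h_true_seq=h, generating_patterns=gen_patterns,
                          planted_categorization=planted, seed=seed)


# ---------------------------------------------------------------------------
# Context index of a genome (for mutation placement)
# ---------------------------------------------------------------------------

def _context_index(genome: SyntheticGenome, exome_only: bool):
    """Positions grouped by pyrimidine-collapsed 7-mer context id.

    Context id = left-flank code * 128 + (ref==T) * 64 + right-flank code.
    Returns (cids sorted-unique boundaries) as a dict of arrays.
    """
    rows = []
    for ci, (chrom, s) in enumerate(genome.chroms.items()):
        codes = _CODE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]
        if codes.size < 7:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, 7)
        ok = (win >= 0).all(axis=1)
        if exome_only:
            mask = np.zeros(codes.size, dtype=bool)
            sub = genome.exome[genome.exome["chrom"] == chrom]
            for r in sub.itertuples(index=False):
                mask[int(r.start):int(r.end)] = True
            ok &= mask[3:codes.size - 3]
        centers = np.nonzero(ok)[0] + 3
        w = win[ok].astype(np.int64)
        purine = (w[:, 3] == 0) | (w[:, 3] == 2)
        w[purine] = 3 - w[purine][:, ::-1]
        fl = w[:, 0] * 16 + w[:, 1] * 4 + w[:, 2]
        fr = w[:, 4] * 16 + w[:, 5] * 4 + w[:, 6]
        cid = fl * 128 + (w[:, 3] == 3) * 64 + fr
        rows.append((np.full(centers.size, ci), centers, purine, cid))
    chrom_ids = np.concatenate([r[0] for r in rows])
    centers = np.concatenate([r[1] for r in rows])
    purine = np.concatenate([r[2] for r in rows])
    cid = np.concatenate([r[3] for r in rows])
    order = np.argsort(cid, kind="stable")
    cid = cid[order]
    bounds = np.searchsorted(cid, np.arange(8193))
    return {"chrom_ids": chrom_ids[order], "centers": centers[order],
            "purine": purine[order], "bounds": bounds,
            "chrom_names": list(genome.chroms.keys())}


def _seq_to_context(seq_idx: np.ndarray):
    fr = seq_idx % 64
    rest = seq_idx // 64
    alt_rank = rest % 3
    rest //= 3
    ref_bit = rest % 2
    fl = rest // 2
    return fl * 128 + ref_bit * 64 + fr, ref_bit, alt_rank


def _available_mask(index) -> np.ndarray:
    """Boolean over the 24,576 universe: context present in the genome."""
    counts = np.diff(index["bounds"])
    cids, _, _ = _seq_to_context(np.arange(UNIVERSE_SIZE))
    return counts[cids] > 0


# ---------------------------------------------------------------------------
# Cohorts and expression
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohorts:
    wgs_records: pd.DataFrame
    wes_records: pd.DataFrame
    expression: pd.DataFrame            # WES samples x genes
    gene_sets: dict                     # name -> list of gene ids
    w_true_wgs: np.ndarray              # (n_wgs, K) relative exposures
    w_true_wes: np.ndarray
    coupling: np.ndarray                # (K, n_coupled) linear map B


def _draw_records(index, seq_dist, n_samples, burden_mean, exposures,
                  prefix, rng):
    """Draw Poisson mutation burdens per sample and place each mutation at
    a genome position carrying its drawn 7-mer context.

    Sequences whose context is absent from the (small) genome get zero
    probability and the distribution is renormalized.
    """
    univ = universe()
    available = _available_mask(index)
    records = []
    for j in range(n_samples):
        n_mut = int(rng.poisson(burden_mean))
        p = exposures[j] @ seq_dist
        p = np.where(available, p, 0.0)
        p /= p.sum()
        seqs = rng.choice(UNIVERSE_SIZE, size=n_mut, p=p)
        cids, _, _ = _seq_to_context(seqs)
        for s, cid in zip(seqs, cids):
            lo, hi = index["bounds"][cid], index["bounds"][cid + 1]
            pick = int(rng.integers(lo, hi))
            chrom = index["chrom_names"][index["chrom_ids"][pick]]
            pos0 = int(index["centers"][pick])
            ref_c, alt_c = BASES[univ[s, 3]], BASES[univ[s, 4]]
            if index["purine"][pick]:
                ref_c, alt_c = COMPLEMENT[ref_c], COMPLEMENT[alt_c]
            records.append((f"{prefix}{j:03d}", chrom, pos0 + 1, ref_c, alt_c))
    return pd.DataFrame(records, columns=["sample_id", "chromosome",
                                          "position", "reference_allele",
                                          "mutated_allele"])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def expression_from_exposures(w_rel: np.ndarray, coupling: np.ndarray,
                              coupling_strength: float, n_control: int,
                              noise_sd: float, rng: np.random.Generator):
    """Non-negative expression linearly coupled to relative exposures.

    Coupled ("DDR-like") genes get softplus(coupling_strength * z-scored
    linear map + noise); control genes are pure noise through the same
    link.
    """
    signal = w_rel @ coupling
    sd = signal.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (signal - signal.mean(axis=0)) / sd
    n = w_rel.shape[0]
    coupled = _softplus(coupling_strength * z
                        + noise_sd * rng.normal(size=z.shape))
    control = _softplus(rng.normal(size=(n, n_control)))
    return coupled, control


def simulate_cohort(genome: SyntheticGenome, truth: SyntheticTruth,
                    n_wgs: int = 30, n_wes: int = 30,
                    burden_mean: float = 300.0,
                    exposure_alpha: float = 0.8,
                    coupling_strength: float = 3.0,
                    n_coupled_genes: int = 30, n_control_genes: int = 30,
                    noise_sd: float = 0.5, seed: int = 0) -> SyntheticCohorts:
    """Generate WGS and WES mutation cohorts plus coupled expression.

    WES mutations are restricted to exome positions and the WES burden is
    scaled down by the exome/genome eligible-position ratio, mimicking
    real sparsity.  Expression exists only for WES samples.
    """
    rng = np.random.default_rng(seed)
    k = truth.h_true_seq.shape[0]
    idx_g = _context_index(genome, exome_only=False)
    idx_e = _context_index(genome, exome_only=True)
    w_wgs = rng.dirichlet(np.full(k, exposure_alpha), size=n_wgs)
    w_wes = rng.dirichlet(np.full(k, exposure_alpha), size=n_wes)
    wgs = _draw_records(idx_g, truth.h_true_seq, n_wgs, burden_mean,
                        w_wgs, "WGS", rng)
    ratio = idx_e["centers"].size / idx_g["centers"].size
    wes = _draw_records(idx_e, truth.h_true_seq, n_wes,
                        burden_mean * ratio, w_wes, "WES", rng)
    coupling = rng.normal(size=(k, n_coupled_genes))
    coupled, control = expression_from_exposures(
        w_wes, coupling, coupling_strength, n_control_genes, noise_sd, rng)
    ddr_genes = [f"DDRg{i:03d}" for i in range(n_coupled_genes)]
    ctl_genes = [f"CTLg{i:03d}" for i in range(n_control_genes)]
    expr = pd.DataFrame(np.hstack([coupled, control]),
                        index=[f"WES{j:03d}" for j in range(n_wes)],
                        columns=ddr_genes + ctl_genes)
    return SyntheticCohorts(wgs_records=wgs, wes_records=wes,
                            expression=expr,
                            gene_sets={"DDR": ddr_genes, "control": ctl_genes},
                            w_true_wgs=w_wgs, w_true_wes=w_wes,
                            coupling=coupling)


# ---------------------------------------------------------------------------
# The small fixture used throughout the test suites
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    genome: SyntheticGenome
    truth: SyntheticTruth
    cohorts: SyntheticCohorts
    seed: int
    wgs_sequences: CohortSequences = field(default=None)
    wes_sequences: CohortSequences = field(default=None)

    def dataset_bundle(self, name: str = "synthetic", k_star: int | None = None,
                       gene_set: str = "DDR", fold_seed: int = 0,
                       nmf_seed: int = 0) -> DatasetBundle:
        e = self.cohorts.expression[self.cohorts.gene_sets[gene_set]]
        return DatasetBundle(
            name=name, wgs=self.wgs_sequences, wes=self.wes_sequences,
            expression=e.to_numpy(float),
            opp_idx_genome=opportunity_sequence_indices(self.genome),
            opp_idx_exome=opportunity_sequence_indices(self.genome,
                                                       self.genome.exome),
            k_star=k_star if k_star is not None
            else self.truth.h_true_seq.shape[0],
            fold_seed=fold_seed, nmf_seed=nmf_seed)


def fixture_small(seed: int = 0, genome_length: int = 200_000,
                  n_wgs: int = 30, n_wes: int = 30, k_true: int = 3,
                  burden_mean: float = 300.0,
                  coupling_strength: float = 3.0,
                  noise_sd: float = 0.5) -> Fixture:
    """Deterministic mini-dataset: 200 kb genome, 30 WGS + 30 WES samples,
    three planted signatures; used by all module test suites."""
    genome = simulate_genome(length=genome_length, seed=seed)
    truth = simulate_truth(k_true=k_true, seed=seed + 1)
    cohorts = simulate_cohort(genome, truth, n_wgs=n_wgs, n_wes=n_wes,
                              burden_mean=burden_mean,
                              coupling_strength=coupling_strength,
                              noise_sd=noise_sd, seed=seed + 2)
    fix = Fixture(genome=genome, truth=truth, cohorts=cohorts, seed=seed)
    fix.wgs_sequences = extract_cohort(genome, cohorts.wgs_records)
    fix.wes_sequences = extract_cohort(genome, cohorts.wes_records)
    return fix


def planted_correlation_oracle(k_true: int = 3, n_samples: int = 30,
                               coupling_strength: float = 3.0,
                               noise_sd: float = 0.5,
                               n_coupled_genes: int = 30,
                               exposure_alpha: float = 0.8,
                               n_folds: int = 10, regularization: float = 0.1,
                               n_reps: int = 20, seed: int = 0) -> float:
    """Monte-Carlo estimate of the held-out CCA correlation between the
    *true* exposures and expression under the generative model.

    This is the oracle the pipeline's estimated-exposure correlation is
    compared against; it never touches NMF or NNLS.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        w = rng.dirichlet(np.full(k_true, exposure_alpha), size=n_samples)
        coupling = rng.normal(size=(k_true, n_coupled_genes))
        coupled, _ = expression_from_exposures(
            w, coupling, coupling_strength, 1, noise_sd, rng)
        vals.append(cca_test_correlation(
            w, coupled, n_folds=n_folds, regularization=regularization,
            seed=int(rng.integers(0, 2**31 - 1))))
    return float(np.mean(vals))
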