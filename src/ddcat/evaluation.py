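"""Out-of-sample benchmarking of categorizations and comparison of
discovered signatures to a reference catalog over the standard categories."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (MutationCatalog, normalize_rows, renormalize_signatures)
from .factorization import kl_divergence, nmf_kl, nnls_exposures
from .fitness import cca_test_correlation
from .patterns import Categorization, TransformationMatrix, transformation_matrix


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


def transform_signature(s: np.ndarray, t: TransformationMatrix | np.ndarray
                        ) -> np.ndarray:
    """Map a signature over a categorization's categories onto the
    standard categories: S' = S T.

    If mass fell on empty source categories (all-zero T rows) the result
    is renormalized with a warning.
    """
    mat = t.matrix if isinstance(t, TransformationMatrix) else np.asarray(t, float)
    s = np.atleast_2d(np.asarray(s, float))
    if s.shape[1] != mat.shape[0]:
        raise ValueError(f"signature length {s.shape[1]} != T rows {mat.shape[0]}")
    out = s @ mat
    in_mass = s.sum(axis=1)
    out_mass = out.sum(axis=1)
    lost = in_mass - out_mass > 1e-9
    if np.any(lost):
        warnings.warn("signature mass fell on empty categories; renormalizing")
        out[lost] = out[lost] / out_mass[lost, None]
    return out[0] if out.shape[0] == 1 else out


@dataclass
class ReferenceSignatureSet:
    """Reference signatures (rows) over the 96 standard categories."""

    matrix: np.ndarray
    names: list[str]

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(float), names=list(df.index))

    def to_tsv(self, path, category_labels) -> None:
        pd.DataFrame(self.matrix, index=self.names,
                     columns=category_labels).to_csv(path, sep="\t",
                                                     index_label="signature")


@dataclass
class SignatureMatch:
    signature_index: int
    matches: list[tuple[str, float]]    # (reference name, cosine), descending
    sub_threshold: bool


def match_to_reference(h: np.ndarray, t: TransformationMatrix | np.ndarray,
                       ref: ReferenceSignatureSet,
                       threshold: float = 0.8) -> list[SignatureMatch]:
    """Match each transformed signature to reference signatures by cosine.

    All matches above ``threshold`` are reported, best first; when none
    exceed it, the single best match is reported flagged sub-threshold.
    """
    h = np.atleast_2d(np.asarray(h, float))
    out = []
    for i in range(h.shape[0]):
        s_std = transform_signature(h[i], t)
        sims = [(name, cosine_similarity(s_std, ref.matrix[j]))
                for j, name in enumerate(ref.names)]
        sims.sort(key=lambda x: -x[1])
        above = [m for m in sims if m[1] > threshold]
        if above:
            out.append(SignatureMatch(i, above, sub_threshold=False))
        else:
            out.append(SignatureMatch(i, sims[:1], sub_threshold=True))
    return out


def prevalence_ranking(ref: ReferenceSignatureSet,
                       catalog: MutationCatalog | np.ndarray) -> list[str]:
    """Rank reference signatures by mean NNLS exposure, most prevalent first.

    Exposures of all reference signatures are refit jointly per sample on
    the row-normalized standard-categorization catalog.
    """
    v = normalize_rows(catalog)
    if v.shape[1] != ref.matrix.shape[1]:
        raise ValueError("catalog and reference live in different category spaces")
    w = nnls_exposures(v, ref.matrix)
    order = np.argsort(-w.mean(axis=0), kind="stable")
    return [ref.names[i] for i in order]


@dataclass
class EvaluationReport:
    categorization: str
    k_values: list[int]
    reconstruction_error: dict = field(default_factory=dict)  # K -> KL error
    cca_correlation: dict = field(default_factory=dict)       # (K, gene set) -> r
    reference_matches: dict = field(default_factory=dict)     # K -> matches

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.k_values:
            row = {"K": k, "reconstruction_error": self.reconstruction_error.get(k)}
            for (kk, gs), r in self.cca_correlation.items():
                if kk == k:
                    row[f"cca_{gs}"] = r
            rows.append(row)
        return pd.DataFrame(rows)


def out_of_sample_evaluation(cat: Categorization,
                             wgs_catalog: MutationCatalog,
                             wes_catalog: MutationCatalog,
                             expression: dict[str, np.ndarray],
                             k_list,
                             u_wgs, u_wes,
                             n_restarts: int = 10,
                             n_folds: int = 10,
                             regularization: float = 0.1,
                             nmf_seed: int = 0, fold_seed: int = 0,
                             reference: ReferenceSignatureSet | None = None,
                             match_threshold: float = 0.8,
                             nmf_max_iter: int = 2000,
                             nmf_tol: float = 1e-6) -> EvaluationReport:
    """Per-K out-of-sample evaluation of a categorization.

    Per K: best-of-``n_restarts`` KL-NMF on the WGS catalog, opportunity
    renormalization to the exome regime, NNLS refitting on the held-out
    WES catalog, KL reconstruction error of the WES fit, and held-out CCA
    correlation for each gene-set expression matrix.
    """
    v_wgs = normalize_rows(wgs_catalog)
    v_wes = normalize_rows(wes_catalog)
    report = EvaluationReport(categorization=cat.name,
                              k_values=[int(k) for k in k_list])
    t = transformation_matrix(cat) if reference is not None else None
    for k in report.k_values:
        if k > min(v_wgs.shape):
            raise ValueError(f"K={k} exceeds the WGS sample/category count")
        res = nmf_kl(v_wgs, k, n_restarts=n_restarts, seed=nmf_seed + k,
                     max_iter=nmf_max_iter, tol=nmf_tol)
        h = renormalize_signatures(res.h, u_wgs, u_wes)
        w = nnls_exposures(v_wes, h)
        report.reconstruction_error[k] = kl_divergence(v_wes, w, h,
                                                       floor=1e-12)
        for gene_set, e in expression.items():
            report.cca_correlation[(k, gene_set)] = cca_test_correlation(
                w, e, n_folds=n_folds, regularization=regularization,
                seed=fold_seed)
        if reference is not None:
            report.reference_matches[k] = match_to_reference(
                h, t, reference, threshold=match_threshold)
    return report
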