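"""Mutational-signature analysis over the 96 trinucleotide classes.

De novo signature discovery by non-negative matrix factorization
(multiplicative updates, Frobenius loss) with cophenetic-coefficient rank
selection over consensus clusterings of random restarts; non-negative
least-squares refitting against a fixed signature panel; cosine comparison;
and per-signature mutation densities.

The shipped reference panel (``load_reference_signatures``) contains
synthetic stand-in profiles — three COSMIC-flavoured references (SBS5-like
clock, SBS18-like C>A, SBS44-like MMR) and two MDA-amplification artifact
profiles (scE-like, scF-like C>T) — constructed for testing, not downloaded
from COSMIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .contexts import CONTEXT_96, class_of_variant

_SIG_CACHE: pd.DataFrame | None = None


def load_reference_signatures() -> pd.DataFrame:
    """Shipped synthetic reference/artifact signatures (96 x K DataFrame).

    Columns: SBS5_like, SBS18_like, SBS44_like, scE_like, scF_like; each
    column is a probability distribution over the 96 classes.
    """
    global _SIG_CACHE
    if _SIG_CACHE is None:
        with resources.files("cardiosnv.data").joinpath(
            "synthetic_reference_signatures.tsv"
        ).open() as fh:
            df = pd.read_csv(fh, sep="\t").set_index("context")
        df = df / df.sum(axis=0)  # exact renormalization after file rounding
        _SIG_CACHE = df.loc[list(CONTEXT_96)]
    return _SIG_CACHE


def trinucleotide_context(chrom_seq: str, pos: int, ref: str, alt: str) -> str:
    """96-class of a variant (pyrimidine-strand representation)."""
    return class_of_variant(chrom_seq, pos, ref, alt)


def context_matrix(variants: pd.DataFrame, reference, cell_ids=None) -> pd.DataFrame:
    """Tabulate per-cell 96-class counts.

    ``variants`` needs columns cell_id, chrom, pos, ref, alt;
    ``reference`` is a :class:`~cardiosnv.synthetic.ReferenceGenome`.
    """
    labels = [
        class_of_variant(reference.sequences[c], int(p), r, a)
        for c, p, r, a in zip(
            variants["chrom"], variants["pos"], variants["ref"], variants["alt"]
        )
    ]
    df = pd.DataFrame({"cell_id": variants["cell_id"].to_numpy(), "context": labels})
    mat = (
        df.groupby(["cell_id", "context"]).size().unstack(fill_value=0)
        .reindex(columns=list(CONTEXT_96), fill_value=0)
    )
    if cell_ids is not None:
        mat = mat.reindex(index=list(cell_ids), fill_value=0)
    return mat.astype(np.int64)


def cosine(a, b) -> float:
    """Cosine similarity of two non-negative 96-vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(a @ b / (na * nb))


def _mu_nmf(X, k, rng, max_iter=2000, tol=1e-6, track=None):
    """Multiplicative-update NMF, Frobenius loss. Returns (W, H, err)."""
    n, m = X.shape
    scale = np.sqrt(X.mean() / k)
    W = rng.random((n, k)) * scale + 1e-9
    H = rng.random((k, m)) * scale + 1e-9
    eps = 1e-12
    prev = np.linalg.norm(X - W @ H)
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        err = np.linalg.norm(X - W @ H)
        if track is not None:
            track.append(err)
        if prev - err < tol * max(prev, 1.0):
            prev = err
            break
        prev = err
    return W, H, prev


@dataclass
class SignatureSet:
    """K x 96 row-stochastic signatures with per-cell exposures and metrics."""

    signatures: pd.DataFrame  # K x 96, rows sum to 1
    exposures: pd.DataFrame   # cells x K, counts scale
    rank: int
    metrics: pd.DataFrame     # per candidate rank: cophenetic, recon_error


def nmf_decompose(
    matrix: pd.DataFrame,
    rank_range=range(2, 6),
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> SignatureSet:
    """De novo signature discovery with cophenetic rank selection.

    For each candidate rank, ``restarts`` random initializations are run;
    the consensus matrix over restarts (cells co-assigned to the same
    dominant signature) yields the cophenetic correlation; the selected rank
    maximizes it (ties break toward the smaller rank). The best restart by
    reconstruction error provides the factors; signatures are L1-normalized
    with exposures rescaled to preserve the product.
    """
    X = matrix.to_numpy(dtype=float)
    if X.sum() == 0:
        raise ValueError("all-zero context matrix")
    low = (X.sum(axis=1) < 50).sum()
    if X.shape[0] < 2 or low:
        warnings.warn("context matrix is small; NMF may be unstable")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    results = {}
    rows = []
    for k in rank_range:
        best = None
        consensus = np.zeros((n, n))
        for _ in range(restarts):
            W, H, err = _mu_nmf(X, k, rng, max_iter=max_iter, tol=tol)
            assign = W.argmax(axis=1)
            consensus += assign[:, None] == assign[None, :]
            if best is None or err < best[2]:
                best = (W, H, err)
        consensus /= restarts
        if n >= 3:
            dist = squareform(1.0 - consensus, checks=False)
            Z = linkage(dist, method="average")
            with np.errstate(invalid="ignore"):
                coph = cophenet(Z, dist)[0]
            if not np.isfinite(coph):  # perfectly stable consensus
                coph = 1.0
        else:
            coph = 1.0
        results[k] = best
        rows.append({"rank": k, "cophenetic": coph, "recon_error": best[2]})
    metrics = pd.DataFrame(rows)
    sel = int(metrics.loc[metrics["cophenetic"].idxmax(), "rank"])
    # ties toward the smaller rank
    top = metrics[np.isclose(metrics["cophenetic"], metrics["cophenetic"].max())]
    sel = int(top["rank"].min())
    W, H, _ = results[sel]
    norms = H.sum(axis=1)
    norms[norms == 0] = 1.0
    Hn = H / norms[:, None]
    Wn = W * norms[None, :]
    sig_names = [f"S{i + 1}" for i in range(sel)]
    return SignatureSet(
        signatures=pd.DataFrame(Hn, index=sig_names, columns=list(CONTEXT_96)),
        exposures=pd.DataFrame(Wn, index=matrix.index, columns=sig_names),
        rank=sel,
        metrics=metrics,
    )


def match_signatures(found: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Optimal assignment of discovered signatures to references.

    Hungarian assignment on cosine distance; ``found`` is K x 96 (rows),
    ``reference`` 96 x R (columns). Returns found name, matched reference,
    cosine.
    """
    from scipy.optimize import linear_sum_assignment

    F = found.to_numpy(dtype=float)
    R = reference.to_numpy(dtype=float).T
    C = np.zeros((F.shape[0], R.shape[0]))
    for i in range(F.shape[0]):
        for j in range(R.shape[0]):
            C[i, j] = 1.0 - cosine(F[i], R[j])
    ri, cj = linear_sum_assignment(C)
    return pd.DataFrame(
        {
            "signature": found.index[ri],
            "reference": reference.columns[cj],
            "cosine": 1.0 - C[ri, cj],
        }
    )


def refit_fixed(profile, fixed_signatures: pd.DataFrame) -> tuple[pd.Series, float]:
    """Non-negative least-squares refit of a 96-profile onto fixed signatures.

    The profile is L1-normalized, fit against the row-stochastic signature
    panel by NNLS, and the weights renormalized to sum to 1. Returns
    (weights, residual L2 norm of the normalized fit).
    """
    if fixed_signatures.shape[1] == 0 and fixed_signatures.shape[0] == 0:
        raise ValueError("empty signature panel")
    A = fixed_signatures.to_numpy(dtype=float)
    if A.shape[0] == 96:  # accept 96 x K column layout
        A = A.T
        names = list(fixed_signatures.columns)
    else:
        names = list(fixed_signatures.index)
    if len(names) == 0:
        raise ValueError("empty signature panel")
    y = np.asarray(profile, dtype=float)
    tot = y.sum()
    if tot == 0:
        raise ValueError("empty mutation profile")
    y = y / tot
    w, res = nnls(A.T, y)
    s = w.sum()
    if s > 0:
        w = w / s
    return pd.Series(w, index=names), float(res)


def signature_density(overall_density: float, weights: pd.Series) -> pd.Series:
    """Split an overall sSNV density into per-signature densities.

    density_k = overall x w_k; conserves the total by construction.
    """
    w = pd.Series(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return overall_density * w
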