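"""Weighted-degree-kernel SVM splice-site classifiers.

One classifier is trained per (dimer, role).  Positive examples are annotated
splice sites carrying the dimer; negative examples are every other in-gene
occurrence of the dimer on the gene's coding strand.  Each example is a
fixed-geometry nucleotide window with the dimer at a fixed offset: donors use
``exon_side + 2 + intron_side`` windows, acceptors ``intron_side + 2 +
exon_side``.  Windows from minus-strand genes are reverse complements of the
forward-axis slices.

The weighted-degree kernel scores two equal-length windows by their shared
position-aligned substrings up to degree D,

    k(x, y) = sum_{d=1..D} beta_d * sum_i [x[i:i+d] == y[i:i+d]],

with the standard weighting beta_d = 2 (D - d + 1) / (D (D + 1)).  A maximal
run of matching positions of length r contributes sum_{d<=min(r,D)} beta_d at
each position of the run, which the implementation exploits to evaluate the
kernel with one pass over positions.  Positional shifts and within-k-mer
mismatches are available as grid options and default off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .coords_io import GeneModel, chrom_length, fetch, revcomp
from .junctions import SpliceSite, sites_from_gene_models

log = logging.getLogger(__name__)


def default_betas(degree: int) -> tuple[float, ...]:
    """beta_d = 2 (D - d + 1) / (D (D + 1)), the standard degree weighting."""
    return tuple(2.0 * (degree - d + 1) / (degree * (degree + 1)) for d in range(1, degree + 1))


@dataclass(frozen=True)
class WDKernelParams:
    degree: int = 4
    shift: int = 0
    mismatch: int = 0
    exon_side: int = 12
    intron_side: int = 15
    betas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.betas is not None and len(self.betas) != self.degree:
            raise ValueError("need one beta per degree")
        if self.betas is not None and any(b <= 0 for b in self.betas):
            raise ValueError("betas must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(
            self.betas if self.betas is not None else default_betas(self.degree)
        )

    @property
    def window_length(self) -> int:
        return self.exon_side + 2 + self.intron_side


@dataclass(frozen=True)
class SiteExample:
    window: str
    label: int  # +1 positive, -1 negative
    chrom: str = "."
    strand: str = "+"
    boundary: int = -1


# ---------------------------------------------------------------------------
# windows


def site_window(
    genome, chrom: str, strand: str, boundary: int, role: str, params: WDKernelParams
) -> str | None:
    """Extract the classifier window around a site boundary; None if it would
    run off the chromosome."""
    e, i = params.exon_side, params.intron_side
    clen = chrom_length(genome, chrom)
    if role == "donor":
        if strand == "+":
            lo, hi = boundary - e, boundary + 2 + i
            if lo < 0 or hi > clen:
                return None
            return fetch(genome, chrom, lo, hi)
        lo, hi = boundary - 2 - i, boundary + e
        if lo < 0 or hi > clen:
            return None
        return revcomp(fetch(genome, chrom, lo, hi))
    if strand == "+":
        lo, hi = boundary - 2 - i, boundary + e
        if lo < 0 or hi > clen:
            return None
        return fetch(genome, chrom, lo, hi)
    lo, hi = boundary - e, boundary + 2 + i
    if lo < 0 or hi > clen:
        return None
    return revcomp(fetch(genome, chrom, lo, hi))


def _dimer_occurrences(
    genome, gene: GeneModel, dimer: str, role: str
) -> list[int]:
    """Boundary coordinates of every coding-strand occurrence of the dimer in
    the gene span, interpreted in the given role."""
    gi = gene.interval
    seq = fetch(genome, gi.chrom, gi.start, gi.end)
    target = dimer if gi.strand == "+" else revcomp(dimer)
    boundaries = []
    pos = seq.find(target)
    while pos != -1:
        g = gi.start + pos
        if gi.strand == "+":
            boundary = g if role == "donor" else g + 2
        else:
            boundary = g + 2 if role == "donor" else g
        boundaries.append(boundary)
        pos = seq.find(target, pos + 1)
    return boundaries


def extract_examples(
    genome,
    models: Iterable[GeneModel],
    dimer: str,
    role: str,
    params: WDKernelParams,
) -> list[SiteExample]:
    """Positive examples from annotated sites with the dimer, negatives from
    all other in-gene occurrences of the dimer."""
    models = list(models)
    annotated = sites_from_gene_models(models, genome)
    known: set[tuple] = set()
    for sites in annotated.values():
        for s in sites:
            if s.role == role and s.dimer == dimer:
                known.add((s.chrom, s.strand, s.boundary))
    out: dict[tuple, SiteExample] = {}
    for gene in models:
        gi = gene.interval
        for boundary in _dimer_occurrences(genome, gene, dimer, role):
            loc = (gi.chrom, gi.strand, boundary)
            if loc in out:
                continue
            window = site_window(genome, gi.chrom, gi.strand, boundary, role, params)
            if window is None:
                continue
            label = 1 if loc in known else -1
            out[loc] = SiteExample(window, label, gi.chrom, gi.strand, boundary)
    examples = list(out.values())
    n_pos = sum(1 for e in examples if e.label == 1)
    if n_pos == 0:
        log.warning("no positive %s/%s examples; training would be skipped", dimer, role)
    return examples


# ---------------------------------------------------------------------------
# kernel


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("all windows must have equal length")
    return np.vstack(
        [np.frombuffer(w.upper().encode("ascii"), dtype=np.uint8) for w in windows]
    )


def _degree_gain_table(L: int, weights: np.ndarray) -> np.ndarray:
    """g[r] = sum_{d <= min(r, D)} beta_d, the per-position gain of being in a
    matching run that has currently extended to length r."""
    D = len(weights)
    g = np.zeros(L + 1)
    acc = 0.0
    for r in range(1, L + 1):
        if r <= D:
            acc += weights[r - 1]
        g[r] = acc
    return g


def _wd_exact(A: np.ndarray, B: np.ndarray, weights: np.ndarray) -> np.ndarray:
    L = A.shape[1]
    g = _degree_gain_table(L, weights)
    run = np.zeros((A.shape[0], B.shape[0]), dtype=np.int32)
    K = np.zeros((A.shape[0], B.shape[0]))
    for i in range(L):
        match = A[:, i, None] == B[None, :, i]
        run = (run + 1) * match
        K += g[run]
    return K


def _wd_mismatch(A: np.ndarray, B: np.ndarray, weights: np.ndarray, M: int) -> np.ndarray:
    L = A.shape[1]
    D = len(weights)
    match = (A[:, None, :] == B[None, :, :]).astype(np.int32)  # (nA, nB, L)
    cs = np.concatenate(
        [np.zeros(match.shape[:2] + (1,), dtype=np.int32), np.cumsum(match, axis=2)],
        axis=2,
    )
    K = np.zeros(match.shape[:2])
    for d in range(1, D + 1):
        window = cs[:, :, d:] - cs[:, :, :-d]  # matches in each length-d k-mer
        K += weights[d - 1] * (window >= d - M).sum(axis=2)
    return K


def wd_kernel_matrix(
    A: np.ndarray, B: np.ndarray, params: WDKernelParams
) -> np.ndarray:
    """Kernel matrix between two encoded window sets."""
    if A.shape[1] != B.shape[1]:
        raise ValueError("window length mismatch")
    w = params.weights
    if params.mismatch > 0:
        base = _wd_mismatch(A, B, w, params.mismatch)
    else:
        base = _wd_exact(A, B, w)
    for s in range(1, params.shift + 1):
        delta = 1.0 / (2.0 * s)
        if params.mismatch > 0:
            base += delta * (
                _wd_mismatch(A[:, s:], B[:, :-s], w, params.mismatch)
                + _wd_mismatch(A[:, :-s], B[:, s:], w, params.mismatch)
            )
        else:
            base += delta * (
                _wd_exact(A[:, s:], B[:, :-s], w) + _wd_exact(A[:, :-s], B[:, s:], w)
            )
    return base


def wd_kernel(x: str, y: str, params: WDKernelParams) -> float:
    """Weighted-degree kernel between two windows."""
    if len(x) != len(y):
        raise ValueError("window length mismatch")
    return float(wd_kernel_matrix(encode_windows([x]), encode_windows([y]), params)[0, 0])


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted one half."""
    y = np.asarray(labels)
    return float(roc_auc_score((y > 0).astype(int), np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# training


@dataclass
class SiteClassifier:
    """A trained per-dimer splice-site classifier."""

    dimer: str
    role: str
    params: WDKernelParams
    support_windows: tuple[str, ...]
    dual_coef: np.ndarray
    bias: float
    threshold: float = 0.0
    cv_auc: float | None = None

    def decision_scores(self, windows: Sequence[str]) -> np.ndarray:
        K = wd_kernel_matrix(
            encode_windows(windows), encode_windows(self.support_windows), self.params
        )
        return K @ self.dual_coef + self.bias

    def predict(self, windows: Sequence[str]) -> np.ndarray:
        return self.decision_scores(windows) > self.threshold

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "dimer": self.dimer,
            "role": self.role,
            "params": {
                **asdict(self.params),
                "betas": list(self.params.weights),
            },
            "support_windows": list(self.support_windows),
            "dual_coef": [float(v) for v in self.dual_coef],
            "bias": self.bias,
            "threshold": self.threshold,
            "cv_auc": self.cv_auc,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SiteClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported classifier file version in {path}")
        p = payload["params"]
        params = WDKernelParams(
            degree=p["degree"],
            shift=p["shift"],
            mismatch=p["mismatch"],
            exon_side=p["exon_side"],
            intron_side=p["intron_side"],
            betas=tuple(p["betas"]),
        )
        return cls(
            dimer=payload["dimer"],
            role=payload["role"],
            params=params,
            support_windows=tuple(payload["support_windows"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            bias=payload["bias"],
            threshold=payload["threshold"],
            cv_auc=payload["cv_auc"],
        )


def _slice_windows(
    enc: np.ndarray, role: str, full: WDKernelParams, p: WDKernelParams
) -> np.ndarray:
    """Restrict windows extracted at geometry ``full`` to geometry ``p``."""
    if p.exon_side > full.exon_side or p.intron_side > full.intron_side:
        raise ValueError("grid geometry exceeds extraction geometry")
    if role == "donor":
        lo = full.exon_side - p.exon_side
        hi = full.exon_side + 2 + p.intron_side
    else:
        lo = full.intron_side - p.intron_side
        hi = full.intron_side + 2 + p.exon_side
    return enc[:, lo:hi]


def train_classifier(
    examples: Sequence[SiteExample],
    params_grid: Sequence[WDKernelParams] = (WDKernelParams(),),
    folds: int = 5,
    seed: int = 0,
    c_values: Sequence[float] = (1.0,),
    dimer: str = "GT",
    role: str = "donor",
    extraction_params: WDKernelParams | None = None,
) -> SiteClassifier:
    """Grid-search kernel parameters and regularization by stratified
    cross-validated ROC, then refit the best combination on all data.

    ``extraction_params`` names the geometry the example windows were cut at
    (defaults to the first grid entry); grid geometries must be no wider.
    Class imbalance is handled by per-class error weighting.
    """
    labels = np.asarray([e.label for e in examples])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both positive and negative examples")
    full = extraction_params or params_grid[0]
    enc_full = encode_windows([e.window for e in examples])
    best = None
    for params in params_grid:
        enc = _slice_windows(enc_full, role, full, params)
        K = wd_kernel_matrix(enc, enc, params)
        for C in c_values:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            aucs = []
            for tr, te in skf.split(K, labels):
                clf = SVC(C=C, kernel="precomputed", class_weight="balanced")
                clf.fit(K[np.ix_(tr, tr)], labels[tr])
                scores = clf.decision_function(K[np.ix_(te, tr)])
                aucs.append(roc_auc(scores, labels[te]))
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, params, C, K, enc)
    mean_auc, params, C, K, enc = best
    clf = SVC(C=C, kernel="precomputed", class_weight="balanced")
    clf.fit(K, labels)
    support = clf.support_
    windows = [examples[i].window for i in support]
    if (full.exon_side, full.intron_side) != (params.exon_side, params.intron_side):
        # persist the sliced windows so scoring needs no extraction context
        sliced = _slice_windows(encode_windows(windows), role, full, params)
        windows = ["".join(chr(c) for c in row) for row in sliced]
    log.info(
        "trained %s/%s classifier: D=%d C=%g CV ROC=%.4f (%d SVs)",
        dimer, role, params.degree, C, mean_auc, len(windows),
    )
    return SiteClassifier(
        dimer=dimer,
        role=role,
        params=params,
        support_windows=tuple(windows),
        dual_coef=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        cv_auc=mean_auc,
    )


# ---------------------------------------------------------------------------
# genome scan


def predict_sites(
    genome,
    models: Iterable[GeneModel],
    classifier: SiteClassifier,
    threshold: float | None = None,
    batch_size: int = 2048,
) -> list[SpliceSite]:
    """Score every in-gene occurrence of the classifier's dimer and return
    above-threshold sites; annotated sites are excluded (they are known)."""
    models = list(models)
    thr = classifier.threshold if threshold is None else threshold
    annotated = sites_from_gene_models(models, genome)
    known: set[tuple] = set()
    for sites in annotated.values():
        for s in sites:
            if s.role == classifier.role:
                known.add((s.chrom, s.strand, s.boundary))
    candidates: dict[tuple, str] = {}
    for gene in models:
        gi = gene.interval
        for boundary in _dimer_occurrences(genome, gene, classifier.dimer, classifier.role):
            loc = (gi.chrom, gi.strand, boundary)
            if loc in known or loc in candidates:
                continue
            w = site_window(
                genome, gi.chrom, gi.strand, boundary, classifier.role, classifier.params
            )
            if w is not None:
                candidates[loc] = w
    locs = list(candidates)
    out: list[SpliceSite] = []
    for i in range(0, len(locs), batch_size):
        chunk = locs[i : i + batch_size]
        scores = classifier.decision_scores([candidates[l] for l in chunk])
        for loc, score in zip(chunk, scores):
            if score > thr:
                chrom, strand, boundary = loc
                out.append(
                    SpliceSite(
                        chrom, strand, boundary, classifier.role,
                        classifier.dimer, "predicted", float(score),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# site tables


def write_site_table(sites: Iterable[SpliceSite], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("chrom\tboundary\tstrand\trole\tdimer\tscore\n")
        for s in sites:
            score = "" if s.score is None else f"{s.score:.6g}"
            fh.write(f"{s.chrom}\t{s.boundary}\t{s.strand}\t{s.role}\t{s.dimer}\t{score}\n")
            n += 1
    return n


def read_site_table(path: str | Path) -> list[SpliceSite]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a site table")
        for line in fh:
            chrom, boundary, strand, role, dimer, score = line.rstrip("\n").split("\t")
            out.append(
                SpliceSite(
                    chrom, strand, int(boundary), role, dimer, "predicted",
                    float(score) if score else None,
                )
            )
    return out
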