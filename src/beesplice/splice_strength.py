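"""Maximum-entropy splice-site models and log-odds strength scoring.

A splice-site model is the maximum-entropy probability distribution over
fixed-width motifs constrained to match empirical marginals of a training
set of true sites.  At constraint order 1 the constraints are per-position
base frequencies and the solution is the familiar position-weight
(independence) model.  At order 2 adjacent-pairwise marginals are added;
because the constraint graph is then a chain, the distribution factorizes
over neighbouring positions and both fitting (iterative proportional
scaling) and normalization are exact via dynamic programming — no motif
enumeration is needed even for the 23-nt acceptor window.

Window geometry follows the common donor/acceptor scoring convention:

* donor: 3 exonic + 6 intronic nt (9 total), read 5'→3' across the
  exon|intron boundary;
* acceptor: 20 intronic + 3 exonic nt (23 total), read 5'→3' across the
  intron|exon boundary.

Strength of a site is ``log2(P_model(motif) / P_background(motif))`` with a
0th-order background (genome base frequencies, uniform by default): the
higher the score, the more the window resembles a real splice site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

ALPHABET = "ACGT"
_INDEX = {base: i for i, base in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

__all__ = [
    "SpliceSiteModel",
    "train",
    "score",
    "score_motif",
    "donor_window",
    "acceptor_window",
    "site_width",
    "strength_vs_inclusion",
    "relative_strength_vs_splicing_ratio",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def site_width(site_type: str) -> int:
    if site_type == "donor":
        return DONOR_WIDTH
    if site_type == "acceptor":
        return ACCEPTOR_WIDTH
    raise ValueError(f"unknown site type {site_type!r}")


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc.args[0]!r} in motif {seq!r}") from exc


# ---------------------------------------------------------------------------
# Chain-structured maximum-entropy distribution


class _ChainMaxEnt:
    """Max-entropy distribution over L-mers with chain constraints.

    ``order=1``: per-position marginal constraints; the fixed point of
    iterative scaling is the product of the empirical marginals.
    ``order=2``: adjacent-pairwise marginal constraints; pair potentials are
    fitted by iterative proportional scaling with exact forward-backward
    marginals.
    """

    def __init__(self, length: int, order: int):
        if order not in (1, 2):
            raise ValueError("constraint order must be 1 or 2")
        self.length = length
        self.order = order
        self.unary: np.ndarray | None = None  # (L, 4) position marginals
        self.pair_potentials: np.ndarray | None = None  # (L-1, 4, 4)
        self.log_z: float = 0.0
        self.max_marginal_deviation: float = np.inf

    # -- forward-backward over pair potentials ---------------------------

    def _forward_backward(self):
        psi = self.pair_potentials
        L = self.length
        alpha = np.zeros((L, 4))
        scale = np.zeros(L)
        alpha[0] = 1.0
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for i in range(L - 1):
            alpha[i + 1] = alpha[i] @ psi[i]
            scale[i + 1] = alpha[i + 1].sum()
            if scale[i + 1] == 0:
                raise ZeroDivisionError("degenerate chain: all paths zero")
            alpha[i + 1] /= scale[i + 1]
        beta = np.zeros((L, 4))
        beta[L - 1] = 1.0
        for i in range(L - 2, -1, -1):
            beta[i] = psi[i] @ beta[i + 1]
            s = beta[i].sum()
            if s == 0:
                raise ZeroDivisionError("degenerate chain: all paths zero")
            beta[i] /= s
        log_z = float(np.log(scale).sum())
        return alpha, beta, log_z

    def _pair_marginals(self):
        alpha, beta, log_z = self._forward_backward()
        psi = self.pair_potentials
        out = np.zeros_like(psi)
        for i in range(self.length - 1):
            m = alpha[i][:, None] * psi[i] * beta[i + 1][None, :]
            total = m.sum()
            out[i] = m / total if total > 0 else m
        return out, log_z

    def fit(self, unary_targets, pair_targets=None, tol: float = 1e-4,
            max_iter: int = 500) -> None:
        if self.order == 1:
            targets = np.asarray(unary_targets, dtype=float)
            phi = np.full((self.length, 4), 0.25)
            for _ in range(max_iter):
                current = phi / phi.sum(axis=1, keepdims=True)
                dev = float(np.abs(current - targets).max())
                self.max_marginal_deviation = dev
                if dev == 0.0:
                    break
                with np.errstate(divide="ignore", invalid="ignore"):
                    phi = np.where(current > 0, phi * targets / np.maximum(current, 1e-300), 0.0)
            self.unary = phi / phi.sum(axis=1, keepdims=True)
            return
        targets = np.asarray(pair_targets, dtype=float)
        self.pair_potentials = np.where(targets > 0, 1.0, 0.0)
        # iterative proportional scaling, one factor at a time (parallel
        # updates do not converge); marginals are exact via forward-backward
        for _ in range(max_iter):
            for i in range(self.length - 1):
                current, _ = self._pair_marginals()
                update = np.where(
                    (targets[i] > 0) & (current[i] > 0),
                    targets[i] / np.maximum(current[i], 1e-300),
                    0.0,
                )
                self.pair_potentials[i] *= update
            current, _ = self._pair_marginals()
            dev = float(np.abs(current - targets).max())
            self.max_marginal_deviation = dev
            if dev < tol:
                break
        _, _, self.log_z = self._forward_backward()

    def log2_prob(self, idx: np.ndarray) -> float:
        if self.order == 1:
            probs = self.unary[np.arange(self.length), idx]
            if (probs == 0).any():
                return -np.inf
            return float(np.log2(probs).sum())
        terms = self.pair_potentials[np.arange(self.length - 1), idx[:-1], idx[1:]]
        if (terms == 0).any():
            return -np.inf
        return float((np.log(terms).sum() - self.log_z) / np.log(2))

    def position_marginals(self) -> np.ndarray:
        if self.order == 1:
            return self.unary.copy()
        pair, _ = self._pair_marginals()
        out = np.zeros((self.length, 4))
        out[:-1] = pair.sum(axis=2)
        out[-1] = pair[-1].sum(axis=0)
        return out


@dataclass
class SpliceSiteModel:
    """A fitted max-entropy splice-site motif model."""

    site_type: str
    constraint_order: int
    chain: _ChainMaxEnt
    background_log2: np.ndarray  # (4,) log2 background base probabilities
    empirical_unary: np.ndarray
    empirical_pair: np.ndarray | None = None

    @property
    def width(self) -> int:
        return site_width(self.site_type)

    def log2_prob(self, motif: str) -> float:
        if len(motif) != self.width:
            raise ValueError(
                f"{self.site_type} motif must be {self.width} nt, got {len(motif)}"
            )
        return self.chain.log2_prob(encode(motif))

    def log2_background(self, motif: str) -> float:
        return float(self.background_log2[encode(motif)].sum())

    def score_motif(self, motif: str) -> float:
        """Log-odds strength of one motif against the background."""
        return self.log2_prob(motif) - self.log2_background(motif)

    def training_log_likelihood(self, motifs) -> float:
        """Mean per-motif log2 likelihood of a motif set under the model."""
        return float(np.mean([self.chain.log2_prob(encode(m)) for m in motifs]))


def train(
    site_sequences,
    site_type: str,
    constraint_order: int = 2,
    background: np.ndarray | None = None,
    tol: float = 1e-4,
) -> SpliceSiteModel:
    """Fit a max-entropy model to aligned true-site motif sequences.

    ``background`` is a length-4 base probability vector (the genome's
    0th-order composition); uniform when omitted.
    """
    width = site_width(site_type)
    motifs = list(site_sequences)
    if not motifs:
        raise ValueError("no training sequences")
    idx = np.zeros((len(motifs), width), dtype=np.int64)
    for row, motif in enumerate(motifs):
        if len(motif) != width:
            raise ValueError(
                f"{site_type} motif must be {width} nt, got {len(motif)} ({motif!r})"
            )
        idx[row] = encode(motif)
    n = len(motifs)
    unary = np.zeros((width, 4))
    for i in range(width):
        unary[i] = np.bincount(idx[:, i], minlength=4) / n
    pair = np.zeros((width - 1, 4, 4))
    for i in range(width - 1):
        np.add.at(pair[i], (idx[:, i], idx[:, i + 1]), 1.0)
    pair /= n
    chain = _ChainMaxEnt(width, constraint_order)
    chain.fit(unary, pair, tol=tol)
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
    with np.errstate(divide="ignore"):
        background_log2 = np.log2(bg)
    return SpliceSiteModel(
        site_type=site_type,
        constraint_order=constraint_order,
        chain=chain,
        background_log2=background_log2,
        empirical_unary=unary,
        empirical_pair=pair if constraint_order == 2 else None,
    )


# ---------------------------------------------------------------------------
# Windows and genomic scoring


def donor_window(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str | None:
    """Motif window at a donor site.

    ``pos`` is the 5' intron boundary in genomic coordinates: the intron
    start on ``+``, the intron end on ``-``.  Returns ``None`` when the
    window runs off the chromosome."""
    seq = genome.get(chrom)
    if seq is None:
        return None
    if strand == "+":
        s, e = pos - DONOR_EXONIC, pos + DONOR_INTRONIC
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = pos - DONOR_INTRONIC, pos + DONOR_EXONIC
    if s < 0 or e > len(seq):
        return None
    return reverse_complement(seq[s:e])


def acceptor_window(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str | None:
    """Motif window at an acceptor site (``pos`` = 3' intron boundary:
    intron end on ``+``, intron start on ``-``)."""
    seq = genome.get(chrom)
    if seq is None:
        return None
    if strand == "+":
        s, e = pos - ACCEPTOR_INTRONIC, pos + ACCEPTOR_EXONIC
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = pos - ACCEPTOR_EXONIC, pos + ACCEPTOR_INTRONIC
    if s < 0 or e > len(seq):
        return None
    return reverse_complement(seq[s:e])


def score_motif(model: SpliceSiteModel, motif: str) -> float:
    return model.score_motif(motif)


def score(
    model: SpliceSiteModel,
    genome: dict[str, str],
    chrom: str,
    pos: int,
    strand: str,
) -> float | None:
    """Strength of the site at ``pos``; ``None`` (NA) when the window runs
    off the chromosome end or contains ambiguous bases."""
    window_fn = donor_window if model.site_type == "donor" else acceptor_window
    motif = window_fn(genome, chrom, pos, strand)
    if motif is None:
        return None
    try:
        return model.score_motif(motif)
    except ValueError:
        return None  # ambiguous bases in the window


# ---------------------------------------------------------------------------
# Figure-level comparisons


def _event_site_positions(event):
    """(donor_pos, acceptor_pos) for a CE exon or an IR intron."""
    plus = event.strand != "-"
    if event.kind == "CE":
        return (event.q, event.p) if plus else (event.p, event.q)
    if event.kind == "IR":
        return (event.p, event.q) if plus else (event.q, event.p)
    raise ValueError(f"no fixed donor/acceptor pair for kind {event.kind}")


def _bin_index(value: float, edges) -> int | None:
    """Index of the half-open ratio bin holding value; top edge inclusive,
    values above the last edge land in the last bin (IR ratios may pass 1)."""
    edges = list(edges)
    if value is None or np.isnan(value):
        return None
    for i in range(len(edges) - 1):
        if edges[i] <= value < edges[i + 1]:
            return i
    if value >= edges[-1]:
        return len(edges) - 2
    return None


def _extreme_bin_test(groups: dict[int, list[float]]):
    """Two-sided Mann-Whitney between the lowest and highest occupied bins,
    plus the difference of their medians; NA when under two bins occupied."""
    occupied = sorted(i for i, vals in groups.items() if len(vals) > 0)
    if len(occupied) < 2:
        return None, None
    low = groups[occupied[0]]
    high = groups[occupied[-1]]
    if len(low) < 1 or len(high) < 1:
        return None, None
    combined = np.concatenate([low, high])
    if np.all(combined == combined[0]):
        return 1.0, 0.0
    p = float(mannwhitneyu(low, high, alternative="two-sided").pvalue)
    return p, float(np.median(high) - np.median(low))


DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def strength_vs_inclusion(
    events,
    model_donor: SpliceSiteModel,
    model_acceptor: SpliceSiteModel,
    genome: dict[str, str],
    bins=DEFAULT_BINS,
) -> dict:
    """Splice-site strength across inclusion-ratio bins for CE and IR events.

    Cassette exons contribute their own donor and acceptor scores; retained
    introns contribute the average of their two flanking site scores.
    Returns per-kind bin tables and the Mann-Whitney p-value between the
    lowest and highest occupied bins.
    """
    import pandas as pd

    out = {}
    for kind, score_mode in (("CE", "separate"), ("IR", "average")):
        kind_events = [e for e in events if e.kind == kind]
        donor_bins: dict[int, list[float]] = {i: [] for i in range(len(bins) - 1)}
        acceptor_bins = {i: [] for i in range(len(bins) - 1)}
        avg_bins = {i: [] for i in range(len(bins) - 1)}
        for e in kind_events:
            if e.inclusion_ratio is None:
                continue
            b = _bin_index(e.inclusion_ratio, bins)
            if b is None:
                continue
            dpos, apos = _event_site_positions(e)
            ds = score(model_donor, genome, e.chrom, dpos, e.strand)
            as_ = score(model_acceptor, genome, e.chrom, apos, e.strand)
            if ds is not None:
                donor_bins[b].append(ds)
            if as_ is not None:
                acceptor_bins[b].append(as_)
            if ds is not None and as_ is not None:
                avg_bins[b].append(0.5 * (ds + as_))
        rows = []
        for i in range(len(bins) - 1):
            rows.append(
                {
                    "bin_low": bins[i],
                    "bin_high": bins[i + 1],
                    "n": len(avg_bins[i]) if score_mode == "average" else len(donor_bins[i]),
                    "median_donor": float(np.median(donor_bins[i])) if donor_bins[i] else np.nan,
                    "median_acceptor": float(np.median(acceptor_bins[i])) if acceptor_bins[i] else np.nan,
                    "median_average": float(np.median(avg_bins[i])) if avg_bins[i] else np.nan,
                }
            )
        table = pd.DataFrame(rows)
        if score_mode == "separate":
            p_donor, d_donor = _extreme_bin_test(donor_bins)
            p_acceptor, d_acceptor = _extreme_bin_test(acceptor_bins)
            out[kind] = {
                "table": table,
                "p_donor": p_donor,
                "median_shift_donor": d_donor,
                "p_acceptor": p_acceptor,
                "median_shift_acceptor": d_acceptor,
            }
        else:
            p_avg, d_avg = _extreme_bin_test(avg_bins)
            out[kind] = {
                "table": table,
                "p_average": p_avg,
                "median_shift_average": d_avg,
            }
    return out


def _aeb_competing_positions(event):
    """(major_pos, minor_pos, site_type) for an AEB or ATE event."""
    plus = event.strand != "-"
    n = event.supports.get("N", 0)
    n2 = event.supports.get("N'", 0)
    annotated_major = n >= n2  # ties break toward the annotated/major slot
    if event.kind in ("ALT_DONOR", "ALT_ACCEPTOR"):
        if event.p2 is not None:
            pos_annot, pos_alt = event.p, event.p2
            site = "donor" if plus else "acceptor"
        else:
            pos_annot, pos_alt = event.q, event.q2
            site = "acceptor" if plus else "donor"
        major, minor = (pos_annot, pos_alt) if annotated_major else (pos_alt, pos_annot)
        return major, minor, site
    if event.kind == "AFE":
        # competing donors at the ends of the two first exons
        major = event.q if plus else event.p
        minor = event.q2 if plus else event.p2
        return major, minor, "donor"
    if event.kind == "ALE":
        major = event.p if plus else event.q
        minor = event.p2 if plus else event.q2
        return major, minor, "acceptor"
    raise ValueError(f"kind {event.kind} has no competing sites")


def relative_strength_vs_splicing_ratio(
    events,
    model_donor: SpliceSiteModel,
    model_acceptor: SpliceSiteModel,
    genome: dict[str, str],
    bins=DEFAULT_BINS,
) -> dict:
    """Relative site strength (major − minor) across splicing-ratio bins.

    AEB events compare the annotated and displaced boundary at the moved
    side; ATE events compare the terminal-exon donors (AFE) or acceptors
    (ALE).  Mann-Whitney is computed between the lowest and highest
    occupied splicing-ratio bins.
    """
    import pandas as pd

    out = {}
    families = {
        "AEB": ("ALT_DONOR", "ALT_ACCEPTOR"),
        "ATE": ("AFE", "ALE"),
    }
    for family, kinds in families.items():
        groups: dict[int, list[float]] = {i: [] for i in range(len(bins) - 1)}
        for e in events:
            if e.kind not in kinds or e.splicing_ratio is None:
                continue
            b = _bin_index(e.splicing_ratio, bins)
            if b is None:
                continue
            major_pos, minor_pos, site = _aeb_competing_positions(e)
            model = model_donor if site == "donor" else model_acceptor
            s_major = score(model, genome, e.chrom, major_pos, e.strand)
            s_minor = score(model, genome, e.chrom, minor_pos, e.strand)
            if s_major is None or s_minor is None:
                continue
            groups[b].append(s_major - s_minor)
        rows = [
            {
                "bin_low": bins[i],
                "bin_high": bins[i + 1],
                "n": len(groups[i]),
                "median_relative_score": float(np.median(groups[i])) if groups[i] else np.nan,
            }
            for i in range(len(bins) - 1)
        ]
        p, shift = _extreme_bin_test(groups)
        out[family] = {
            "table": pd.DataFrame(rows),
            "p_extreme_bins": p,
            "median_shift": shift,
        }
    return out
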