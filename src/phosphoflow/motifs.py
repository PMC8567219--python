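"""Sequence-window extraction and iterative motif-x style enrichment.

Windows of 13 residues (+-6 around the phosphorylated residue, termini
padded with '_') are extracted per phosphorylated position; serine- and
threonine-centered windows are analyzed independently.  Motif extraction is
the greedy motif-x iteration: at each step, for every (offset, residue) pair
the binomial tail probability of observing at least the foreground count
given the background frequency at that offset is computed; the most
significant pair is fixed if it passes the p-value cutoff and the restricted
foreground still holds at least ``min_seq`` windows; both pools are then
restricted to matching windows and the search repeats.  A completed motif's
matches are removed from both pools and extraction restarts for further
motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, FormatError
from .classify import enrichment_test
from .sites import PhosphoSite

PAD = "_"
HALF_WIDTH = 6
WINDOW = 2 * HALF_WIDTH + 1


@dataclass
class SequenceWindow:
    """A 13-character sequence window centered on a phosphorylated residue."""

    window: str
    central_residue: str
    source_site: tuple[str, int]

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW:
            raise FormatError(f"window must be {WINDOW} characters")
        if self.window[HALF_WIDTH] != self.central_residue:
            raise FormatError("central character disagrees with central_residue")


@dataclass
class MotifResult:
    """One extracted motif with its counts and scores."""

    motif: str
    fg_matches: int
    bg_matches: int
    score: float  # sum of -log10 p over the accepted position-residue pairs
    fold_enrichment: float
    steps: list[tuple[int, str, float]] = field(default_factory=list)


def extract_windows(
    sites: Iterable[PhosphoSite | tuple[str, int]],
    proteome: Mapping[str, str],
    half_width: int = HALF_WIDTH,
) -> list[SequenceWindow]:
    """One window per phosphorylated residue (multiply phosphorylated sites
    contribute one window per residue), padded with '_' past the termini."""
    windows = []
    for site in sites:
        if isinstance(site, PhosphoSite):
            pid, positions = site.protein_id, site.positions
        else:
            pid, positions = site[0], (site[1],)
        seq = proteome[pid]
        for pos in positions:
            if not 1 <= pos <= len(seq):
                raise FormatError(f"position {pos} exceeds protein {pid}")
            left = seq[max(0, pos - 1 - half_width) : pos - 1].rjust(half_width, PAD)
            right = seq[pos : pos + half_width].ljust(half_width, PAD)
            aa = seq[pos - 1]
            windows.append(SequenceWindow(left + aa + right, aa, (pid, pos)))
    return windows


def _as_char_matrix(windows: Sequence[SequenceWindow | str]) -> np.ndarray:
    rows = [w.window if isinstance(w, SequenceWindow) else w for w in windows]
    if any(len(r) != WINDOW for r in rows):
        raise FormatError(f"all windows must be {WINDOW} characters")
    return np.array([list(r) for r in rows])


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    if p <= 0.0:
        return 0.0 if k > 0 else 1.0
    if p >= 1.0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _format_motif(central: str, fixed: Mapping[int, str]) -> str:
    chars = ["."] * WINDOW
    chars[HALF_WIDTH] = central.lower()
    for off, res in fixed.items():
        chars[HALF_WIDTH + off] = res
    return "".join(chars)


def motifx(
    foreground: Sequence[SequenceWindow | str],
    background: Sequence[SequenceWindow | str],
    central: str,
    min_seq: int = 20,
    p_cutoff: float = 0.01,
    method: str = "binomial",
) -> list[MotifResult]:
    """Greedy iterative motif extraction over windows with the given central
    residue.

    ``method='binomial'`` scores a candidate (offset, residue) by the
    binomial tail of the foreground count with the background frequency as
    success probability (the classic motif-x statistic);
    ``method='hypergeometric'`` uses the hypergeometric tail of drawing the
    foreground from the background.  Candidate order (offset ascending from
    -6 to +6, residue alphabetical, '_' treated as an ordinary symbol) breaks
    ties deterministically.
    """
    if method not in ("binomial", "hypergeometric"):
        raise ConfigError(f"unknown method {method!r}")
    central = central.upper()
    fg_all = _as_char_matrix(foreground) if len(foreground) else np.empty((0, WINDOW), dtype="<U1")
    bg_all = _as_char_matrix(background) if len(background) else np.empty((0, WINDOW), dtype="<U1")
    if fg_all.size == 0 or bg_all.size == 0:
        raise ConfigError("foreground and background must both be non-empty")
    fg_pool = fg_all[fg_all[:, HALF_WIDTH] == central]
    bg_pool = bg_all[bg_all[:, HALF_WIDTH] == central]
    if len(bg_pool) < len(fg_pool):
        raise ConfigError(
            "background smaller than foreground; the background must cover "
            "the foreground"
        )
    offsets = [o for o in range(-HALF_WIDTH, HALF_WIDTH + 1) if o != 0]

    results: list[MotifResult] = []
    while len(fg_pool) >= min_seq and len(bg_pool) > 0:
        fg = fg_pool
        bg = bg_pool
        n_fg0, n_bg0 = len(fg), len(bg)
        fixed: dict[int, str] = {}
        steps: list[tuple[int, str, float]] = []
        while True:
            best: tuple[float, int, str] | None = None
            n, nb = len(fg), len(bg)
            for off in offsets:
                if off in fixed:
                    continue
                col = HALF_WIDTH + off
                fg_col = fg[:, col]
                bg_col = bg[:, col]
                for res in sorted(set(fg_col.tolist())):
                    k = int((fg_col == res).sum())
                    if k == 0:
                        continue
                    if method == "binomial":
                        p_bg = float((bg_col == res).sum()) / nb
                        p = binomial_tail(k, n, p_bg)
                    else:
                        kb = int((bg_col == res).sum())
                        p = float(stats.hypergeom.sf(k - 1, nb, kb, n))
                    if best is None or p < best[0]:
                        best = (p, off, res)
            if best is None:
                break
            p, off, res = best
            k = int((fg[:, HALF_WIDTH + off] == res).sum())
            if p > p_cutoff or k < min_seq:
                break
            fixed[off] = res
            steps.append((off, res, p))
            fg = fg[fg[:, HALF_WIDTH + off] == res]
            bg = bg[bg[:, HALF_WIDTH + off] == res]
            if len(bg) < len(fg):
                raise ConfigError(
                    "background restricted below foreground size; supply a "
                    "background that covers the foreground"
                )
        if not fixed:
            break
        fg_frac = len(fg) / n_fg0
        bg_frac = len(bg) / n_bg0 if len(bg) else 0.0
        results.append(
            MotifResult(
                motif=_format_motif(central, fixed),
                fg_matches=len(fg),
                bg_matches=len(bg),
                score=float(sum(-math.log10(max(p, 1e-300)) for _, _, p in steps)),
                fold_enrichment=(fg_frac / bg_frac) if bg_frac else float("inf"),
                steps=steps,
            )
        )
        # remove the motif's matches from both pools and restart
        fg_match = np.ones(len(fg_pool), dtype=bool)
        bg_match = np.ones(len(bg_pool), dtype=bool)
        for off, res in fixed.items():
            fg_match &= fg_pool[:, HALF_WIDTH + off] == res
            bg_match &= bg_pool[:, HALF_WIDTH + off] == res
        fg_pool = fg_pool[~fg_match]
        bg_pool = bg_pool[~bg_match]
    return results


def threonine_enrichment(
    fg_windows: Sequence[SequenceWindow | str],
    bg_windows: Sequence[SequenceWindow | str],
) -> tuple[float, float]:
    """Fisher exact test of phospho-threonine vs phospho-serine composition
    between foreground and background, restricted to S/T-P motif windows
    (proline immediately after the central residue).

    Returns (odds ratio, p); a zero margin is flagged as nan odds ratio.
    """
    def _counts(windows):
        t = s = 0
        for w in windows:
            win = w.window if isinstance(w, SequenceWindow) else w
            if win[HALF_WIDTH + 1] != "P":
                continue
            c = win[HALF_WIDTH].upper()
            if c == "T":
                t += 1
            elif c == "S":
                s += 1
        return t, s

    fg_t, fg_s = _counts(fg_windows)
    bg_t, bg_s = _counts(bg_windows)
    return enrichment_test([[fg_t, fg_s], [bg_t, bg_s]])
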