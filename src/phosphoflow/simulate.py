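"""Synthetic SILAC evidence, proteome and densitometry generators.

Every downstream stage of the pipeline is tested against data produced here,
with the generating quantities (mixing offset, per-proline conversion factor,
per-site condition effects, dilution curves, proximity effects) returned as
ground truth.  The generative model for a peptide-level evidence record is

    raw log2 H/L = m + n_prolines * c + site_effect + Normal(0, noise_sd)

where ``m`` is the heavy/light mixing offset of the experiment, ``c`` the
per-proline signal loss caused by metabolic arginine-to-proline conversion of
the heavy label, and ``site_effect`` the planted condition effect of the
phosphosite carried by the peptide (0 for unphosphorylated peptides).  A
replicate flagged in ``label_swap`` has its log2 ratio negated before the
heavy/light ratio is written, emulating experiments run with inverted
labeling orientation.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Rough average amino-acid frequencies (order matches AMINO_ACIDS); only the
# qualitative features matter downstream: P near 5% so proline correction is
# exercised, S/T abundant so peptides carry phospho-acceptor residues.
_AA_FREQS = np.array(
    [
        0.072, 0.013, 0.055, 0.062, 0.042, 0.067, 0.022, 0.060, 0.068, 0.092,
        0.021, 0.046, 0.049, 0.039, 0.047, 0.083, 0.058, 0.063, 0.011, 0.030,
    ]
)
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

DILUTION_LABEL = "_dilution_"
NEGATIVE_CONTROL = "NEGATIVE_CONTROL"

EVIDENCE_COLUMNS = [
    "protein",
    "start",
    "sequence",
    "phospho_probs",
    "n_phospho",
    "other_mods",
    "ratio_hl",
    "replicate",
    "setup",
]

Peptide = namedtuple("Peptide", ["sequence", "start", "end"])


# ---------------------------------------------------------------------------
# proteome and digestion
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> dict[str, str]:
    """Generate random protein sequences with tryptic cleavage sites.

    Sequences are drawn over the 20 amino-acid alphabet with realistic
    frequencies and guaranteed to contain at least two internal K/R residues
    so tryptic digestion yields at least two peptides.  Deterministic for a
    fixed seed.
    """
    if n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 20:
        raise ConfigError("minimum protein length must be >= 20")
    if hi < lo:
        raise ConfigError("length_range must be (min, max) with max >= min")
    rng = np.random.default_rng(seed)
    proteome: dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(list(AMINO_ACIDS), size=length, p=_AA_FREQS)
        # ensure a cleavage site roughly every 6-14 residues
        pos = 0
        while pos < length - 3:
            step = int(rng.integers(6, 15))
            pos += step
            if pos < length - 1:
                residues[pos] = "K" if rng.random() < 0.55 else "R"
        seq = "".join(residues)
        if seq[:-1].count("K") + seq[:-1].count("R") < 2:
            # degenerate draw on very short proteins: patch two sites
            chars = list(seq)
            chars[length // 3] = "K"
            chars[2 * length // 3] = "R"
            seq = "".join(chars)
        proteome[f"P{i + 1:04d}"] = seq
    return proteome


def digest_tryptic(
    sequence: str, max_missed: int = 2, min_length: int = 1
) -> list[Peptide]:
    """In-silico Trypsin/P digest: cleave after every K or R, including
    before proline, allowing up to ``max_missed`` missed cleavages.

    Returns peptides with 1-based inclusive start/end coordinates; peptides
    tile the protein at ``max_missed = 0``.
    """
    if not sequence:
        raise ConfigError("sequence must be non-empty")
    fragments: list[Peptide] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            fragments.append(Peptide(sequence[start : i + 1], start + 1, i + 1))
            start = i + 1
    if start < len(sequence):
        fragments.append(Peptide(sequence[start:], start + 1, len(sequence)))
    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + max_missed + 1, len(fragments))):
            seq = "".join(f.sequence for f in fragments[i : j + 1])
            if len(seq) >= min_length:
                peptides.append(Peptide(seq, fragments[i].start, fragments[j].end))
    return peptides


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic evidence table.

    ``site_effect_table`` maps ``(protein_id, positions_tuple, setup)`` to the
    true log2 condition effect of that phosphosite in that setup.  It can be
    built with :func:`plan_site_effects` or supplied directly.
    """

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (200, 400)
    n_evidence: int = 1000
    mixing_offset_m: float = 0.0
    proline_factor_c: float = 0.0
    noise_sd: float = 0.3
    site_effect_table: Mapping[tuple[str, tuple[int, ...], str], float] | None = None
    phospho_fraction: float = 0.5
    setups: tuple[str, ...] = ("SR",)
    replicates: tuple[str, ...] = ("r1", "r2", "r3")
    localization_alpha: float = 4.0
    frac_low_localization: float = 0.0
    label_swap: Mapping[str, bool] = field(default_factory=dict)
    max_missed: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_evidence < 1:
            raise ConfigError("n_evidence must be >= 1")
        if self.protein_length_range[0] < 20:
            raise ConfigError("minimum protein length must be >= 20")
        if not 0 <= self.phospho_fraction <= 1:
            raise ConfigError("phospho_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted; downstream stages must recover it."""

    true_m: float
    true_c: float
    true_site_effects: dict[tuple[str, tuple[int, ...], str], float]
    true_set_labels: dict[tuple[str, tuple[int, ...]], str]


# thresholds shared with the classification stage (twofold cutoff world)
_SET1_MAX = -1.0
_UP_LOG2 = 1.0
_DOWN_LOG2 = -1.0


def _derive_set_label(effects: Mapping[str, float], setups: Sequence[str]) -> str:
    """Class label implied by planted effects under the downstream rules."""
    sr = effects.get(setups[0], 0.0)
    cdc = effects.get(setups[1], 0.0) if len(setups) > 1 else sr
    igo = effects.get(setups[2], 0.0) if len(setups) > 2 else 0.0
    if sr >= _UP_LOG2 and cdc >= _UP_LOG2:
        if igo <= _SET1_MAX:
            return "Set1"
        if _SET1_MAX < igo < 0:
            return "Set2"
        return "other"
    if sr <= _DOWN_LOG2:
        return "decreased"
    return "static"


def plan_site_effects(
    proteome: Mapping[str, str],
    n_set1: int = 0,
    n_set2: int = 0,
    n_static: int = 0,
    n_decreased: int = 0,
    setups: Sequence[str] = ("SR", "cdc55", "SR_igo1igo2"),
    seed: int = 0,
    stp_bias: float = 0.0,
    double_site_fraction: float = 0.15,
) -> tuple[dict[tuple[str, tuple[int, ...], str], float], dict[tuple[str, tuple[int, ...]], str]]:
    """Choose phospho-acceptor positions on tryptic peptides and plant
    class-consistent log2 effects for each requested site class.

    ``stp_bias`` is the probability that an induced (Set1/Set2) site is placed
    on an S/T residue immediately followed by proline, emulating the
    proline-directed substrate context of the phosphatase-controlled sites.
    Effects are jittered within ranges that respect the twofold / |log2|>1
    classification thresholds, so the returned labels are exact by
    construction.
    """
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, int, bool]] = []  # (protein, position, followed-by-P)
    for pid, seq in proteome.items():
        for pep in digest_tryptic(seq, max_missed=0, min_length=6):
            for k, aa in enumerate(pep.sequence):
                if aa in "ST":
                    pos = pep.start + k
                    stp = pos < len(seq) and seq[pos] == "P"
                    candidates.append((pid, pos, stp))
    rng.shuffle(candidates)
    total = n_set1 + n_set2 + n_static + n_decreased
    if total > len(candidates):
        raise ConfigError(
            f"proteome offers {len(candidates)} acceptor residues, "
            f"{total} sites requested"
        )
    stp_pool = [c for c in candidates if c[2]]
    other_pool = [c for c in candidates if not c[2]]

    used: set[tuple[str, int]] = set()

    def _draw(prefer_stp: bool) -> tuple[str, int]:
        pools = (stp_pool, other_pool) if prefer_stp else (other_pool, stp_pool)
        for pool in pools:
            while pool:
                pid, pos, _ = pool.pop()
                if (pid, pos) not in used:
                    used.add((pid, pos))
                    return pid, pos
        raise ConfigError("exhausted phospho-acceptor candidates")

    table: dict[tuple[str, tuple[int, ...], str], float] = {}
    labels: dict[tuple[str, tuple[int, ...]], str] = {}
    specs = (
        [("Set1", True)] * n_set1
        + [("Set2", True)] * n_set2
        + [("static", False)] * n_static
        + [("decreased", False)] * n_decreased
    )
    for cls, induced in specs:
        prefer = induced and rng.random() < stp_bias
        pid, pos = _draw(prefer)
        positions = (pos,)
        if rng.random() < double_site_fraction:
            # try to pair with an adjacent acceptor on the same base peptide
            seq = proteome[pid]
            for off in (1, 2, 3, -1, -2, -3):
                q = pos + off
                if (
                    1 <= q <= len(seq)
                    and seq[q - 1] in "ST"
                    and (pid, q) not in used
                    and not any(seq[j] in "KR" for j in range(min(pos, q) - 1, max(pos, q) - 1))
                ):
                    used.add((pid, q))
                    positions = tuple(sorted((pos, q)))
                    break
        if cls == "Set1":
            eff = {
                setups[0]: rng.uniform(1.2, 3.0),
                setups[1]: rng.uniform(1.1, 2.5),
                setups[2]: rng.uniform(-2.5, -1.05),
            }
        elif cls == "Set2":
            eff = {
                setups[0]: rng.uniform(1.2, 3.0),
                setups[1]: rng.uniform(1.1, 2.5),
                setups[2]: rng.uniform(-0.9, -0.1),
            }
        elif cls == "decreased":
            eff = {setups[0]: rng.uniform(-3.0, -1.1)}
            for s in setups[1:]:
                eff[s] = rng.uniform(-0.5, 0.5)
        else:
            eff = {s: rng.uniform(-0.5, 0.5) for s in setups}
        for s in setups:
            table[(pid, positions, s)] = float(eff.get(s, 0.0))
        label = _derive_set_label(eff, list(setups))
        assert label == cls, "planted effects escaped their class range"
        labels[(pid, positions)] = cls
    return table, labels


def _draw_top_probability(rng: np.random.Generator, alpha: float, low: bool) -> float:
    """Top-assignment localization probability; Beta(alpha, 1)-shaped within
    the band below or above the 0.70 filter threshold."""
    b = rng.beta(alpha, 1.0)
    if low:
        return 0.2 + 0.49 * b  # always strictly below 0.70
    return 0.9 + 0.1 * b  # product of <= 2 such values stays >= 0.70


def _format_prob_string(
    sequence: str, probs: dict[int, float]
) -> str:
    """Inline probability annotation: 'AAS(0.9)PT(0.1)K' with 1-based
    peptide positions as keys."""
    out = []
    for i, aa in enumerate(sequence, start=1):
        out.append(aa)
        if i in probs:
            out.append(f"({probs[i]:.3f})")
    return "".join(out)


def simulate_evidence(
    config: SimulationConfig,
    proteome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a peptide-level evidence table plus its ground truth.

    Phospho records cycle deterministically through the cross product of
    planted sites, setups and replicates (so every matrix cell is covered
    when ``n_evidence`` is large enough); unphosphorylated records cycle
    through (setup, replicate) with random tryptic peptides.  Row order and
    all draws are deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    if proteome is None:
        proteome = generate_proteome(
            config.n_proteins, config.protein_length_range, seed=config.seed
        )

    table = dict(config.site_effect_table or {})
    sites = sorted({(pid, pos) for pid, pos, _ in table})
    n_phospho = int(round(config.n_evidence * config.phospho_fraction))
    if n_phospho > 0 and not sites:
        raise ConfigError(
            "phospho records requested but site_effect_table is empty"
        )
    n_unphos = config.n_evidence - n_phospho

    # digest pool for unphosphorylated records
    pool: list[tuple[str, Peptide]] = []
    for pid, seq in proteome.items():
        for pep in digest_tryptic(seq, config.max_missed, min_length=6):
            pool.append((pid, pep))
    if not pool:
        raise ConfigError("proteome digest produced no peptides of length >= 6")

    # peptides covering each planted site (positions within peptide span)
    covering: dict[tuple[str, tuple[int, ...]], list[Peptide]] = {}
    for pid, positions in sites:
        peps = [
            pep
            for qid, pep in pool
            if qid == pid and all(pep.start <= p <= pep.end for p in positions)
        ]
        if not peps:
            raise ConfigError(f"no tryptic peptide covers site {pid}:{positions}")
        covering[(pid, positions)] = peps

    set_labels = {
        (pid, pos): _derive_set_label(
            {s: table[(pid, pos, s)] for s in config.setups if (pid, pos, s) in table},
            list(config.setups),
        )
        for pid, pos in sites
    }

    rows: list[tuple] = []
    m, c = config.mixing_offset_m, config.proline_factor_c

    combos = [
        (site, setup, rep)
        for site in sites
        for setup in config.setups
        for rep in config.replicates
    ]
    for i in range(n_phospho):
        (pid, positions), setup, rep = combos[i % len(combos)]
        peps = covering[(pid, positions)]
        pep = peps[int(rng.integers(len(peps)))]
        n_pro = pep.sequence.count("P")
        effect = table.get((pid, positions, setup), 0.0)
        raw = m + n_pro * c + effect
        if config.noise_sd > 0:
            raw += rng.normal(0.0, config.noise_sd)
        if config.label_swap.get(rep, False):
            raw = -raw
        low = rng.random() < config.frac_low_localization
        probs: dict[int, float] = {}
        for p in positions:
            probs[p - pep.start + 1] = _draw_top_probability(
                rng, config.localization_alpha, low
            )
            low = False  # one low draw is enough to sink the product
        # decoy candidates: other acceptor residues on the peptide
        for k, aa in enumerate(pep.sequence, start=1):
            if aa in "STY" and k not in probs:
                if rng.random() < 0.5:
                    probs[k] = round(float(rng.uniform(0.0, 0.1)), 3)
        mods = "oxidation" if ("M" in pep.sequence and rng.random() < 0.1) else ""
        rows.append(
            (
                pid,
                pep.start,
                pep.sequence,
                _format_prob_string(pep.sequence, probs),
                len(positions),
                mods,
                2.0 ** raw,
                rep,
                setup,
            )
        )

    group_cycle = [(s, r) for s in config.setups for r in config.replicates]
    for i in range(n_unphos):
        setup, rep = group_cycle[i % len(group_cycle)]
        pid, pep = pool[int(rng.integers(len(pool)))]
        raw = m + pep.sequence.count("P") * c
        if config.noise_sd > 0:
            raw += rng.normal(0.0, config.noise_sd)
        if config.label_swap.get(rep, False):
            raw = -raw
        rows.append((pid, pep.start, pep.sequence, "", 0, "", 2.0 ** raw, rep, setup))

    evidence = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    truth = GroundTruth(
        true_m=m, true_c=c, true_site_effects=table, true_set_labels=set_labels
    )
    return evidence, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Plain key-value sidecar: generating factors, per-(site, setup) effects
    and per-site class labels."""
    with open(path, "w") as fh:
        fh.write(f"m\t{truth.true_m:.10g}\n")
        fh.write(f"c\t{truth.true_c:.10g}\n")
        for (pid, positions, setup), eff in sorted(truth.true_site_effects.items()):
            pos = ";".join(map(str, positions))
            fh.write(f"effect\t{pid}\t{pos}\t{setup}\t{eff:.10g}\n")
        for (pid, positions), label in sorted(truth.true_set_labels.items()):
            pos = ";".join(map(str, positions))
            fh.write(f"label\t{pid}\t{pos}\t{label}\n")


def read_ground_truth(path) -> GroundTruth:
    true_m = true_c = 0.0
    effects: dict[tuple[str, tuple[int, ...], str], float] = {}
    labels: dict[tuple[str, tuple[int, ...]], str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "m":
                true_m = float(parts[1])
            elif parts[0] == "c":
                true_c = float(parts[1])
            elif parts[0] == "effect":
                pos = tuple(int(p) for p in parts[2].split(";"))
                effects[(parts[1], pos, parts[3])] = float(parts[4])
            elif parts[0] == "label":
                pos = tuple(int(p) for p in parts[2].split(";"))
                labels[(parts[1], pos)] = parts[3]
    return GroundTruth(true_m, true_c, effects, labels)


# ---------------------------------------------------------------------------
# densitometry simulation
# ---------------------------------------------------------------------------

DENSITOMETRY_COLUMNS = [
    "blot_id", "bait", "replicate", "channel", "loading", "area", "series",
]

# planted dilution-curve coefficients, log2 signal vs log2 loading,
# highest degree first; quadratic terms keep the curve monotone on [-3, 0]
_CURVES = {
    1: {"me3": (1.0, 8.0), "ha": (1.0, 10.0)},
    2: {"me3": (0.05, 1.0, 8.0), "ha": (0.03, 1.0, 10.0)},
}


def simulate_densitometry(
    n_baits: int,
    n_replicates: int,
    curve_degree: int = 2,
    effect_map: Mapping[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    loading_sd: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate an M-Track densitometry table with a planted dilution curve,
    per-lane loading factors and per-bait proximity effects.

    One blot per replicate; each blot carries a 4-point dilution series of the
    control sample (loadings 1, 1/2, 1/4, 1/8) for both channels plus one
    me3/HA lane pair per bait.  A negative-control bait with effect 0 is
    always included.  Returns the table and the true effect per bait.
    """
    if curve_degree not in (1, 2):
        raise ConfigError("curve_degree must be 1 or 2")
    if n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2 (Welch test downstream)")
    rng = np.random.default_rng(seed)
    baits = [f"B{i + 1:02d}" for i in range(n_baits)]
    effects = {b: 0.0 for b in baits}
    effects[NEGATIVE_CONTROL] = 0.0
    for b, e in (effect_map or {}).items():
        if b not in effects:
            raise ConfigError(f"effect_map names unknown bait {b!r}")
        effects[b] = float(e)
    series = 1 if curve_degree == 2 else 2
    coefs = _CURVES[curve_degree]
    rows: list[tuple] = []
    for r in range(1, n_replicates + 1):
        blot = f"blot{r}"
        rep = f"rep{r}"
        for channel in ("me3", "ha"):
            poly = np.polynomial.Polynomial(coefs[channel][::-1])
            for loading in (1.0, 0.5, 0.25, 0.125):
                area = 2.0 ** float(poly(math.log2(loading)))
                rows.append((blot, DILUTION_LABEL, rep, channel, loading, area, series))
        for bait in [NEGATIVE_CONTROL] + baits:
            load = rng.normal(0.0, loading_sd)
            prox = effects[bait]
            if noise_sd > 0:
                prox += rng.normal(0.0, noise_sd)
            me3_poly = np.polynomial.Polynomial(coefs["me3"][::-1])
            ha_poly = np.polynomial.Polynomial(coefs["ha"][::-1])
            me3_area = 2.0 ** float(me3_poly(load + prox))
            ha_area = 2.0 ** float(ha_poly(load))
            rows.append((blot, bait, rep, "me3", np.nan, me3_area, series))
            rows.append((blot, bait, rep, "ha", np.nan, ha_area, series))
    return pd.DataFrame(rows, columns=DENSITOMETRY_COLUMNS), effects
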