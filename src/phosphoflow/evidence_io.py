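"""Readers and writers for the tabular formats the pipeline touches.

Two evidence dialects are supported:

``simple``
    The package's documented schema, one row per peptide quantification
    event, tab-delimited with header::

        protein  start  sequence  phospho_probs  n_phospho  other_mods
        ratio_hl  replicate  setup

    ``phospho_probs`` is the peptide sequence with localization
    probabilities inlined after candidate residues, e.g. ``AAS(0.9)PT(0.1)K``
    (empty for unphosphorylated peptides); ``n_phospho`` is the number of
    phosphate groups on the peptide.  The assigned phosphorylated positions
    are the ``n_phospho`` highest-probability candidates (ties broken toward
    the N-terminus), mirroring the best-scoring search-engine isoform.

``maxquant-like``
    Maps the columns "Modified sequence", "Proteins", "Start position",
    "Ratio H/L", "Phospho (STY) Probabilities" and "Experiment" onto the same
    record type.  Modification tags use short labels: ``(ph)`` phospho,
    ``(ox)`` oxidation, ``(ac)`` protein N-term acetyl, ``(de)`` deamidation.

All residue coordinates are 1-based inclusive protein positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

SIMPLE_COLUMNS = [
    "protein", "start", "sequence", "phospho_probs", "n_phospho",
    "other_mods", "ratio_hl", "replicate", "setup",
]

MAXQUANT_COLUMNS = {
    "Modified sequence": "modified_sequence",
    "Proteins": "protein",
    "Start position": "start",
    "Ratio H/L": "ratio_hl",
    "Phospho (STY) Probabilities": "phospho_probs",
    "Experiment": "replicate",
}

_MOD_TAGS = {"ox": "oxidation", "ac": "acetyl_nterm", "de": "deamidation"}


@dataclass
class EvidenceRecord:
    """One peptide-level quantification event.

    ``phospho_positions`` and the keys of ``per_position_probability`` are
    1-based protein residue positions; ``ratio_hl`` is the raw heavy/light
    SILAC ratio.  ``log2_corrected`` is filled by the normalization stage.
    """

    protein_id: str
    peptide_start: int
    bare_sequence: str
    modified_sequence: str
    phospho_positions: tuple[int, ...]
    per_position_probability: dict[int, float]
    other_mods: frozenset[str]
    ratio_hl: float
    replicate_id: str
    setup_id: str
    proline_count: int = -1
    log2_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_hl <= 0:
            raise FormatError(f"ratio_hl must be > 0, got {self.ratio_hl}")
        n_pro = self.bare_sequence.count("P")
        if self.proline_count < 0:
            self.proline_count = n_pro
        elif self.proline_count != n_pro:
            raise FormatError("proline_count inconsistent with sequence")
        end = self.peptide_end
        for p in self.phospho_positions:
            if not self.peptide_start <= p <= end:
                raise FormatError(
                    f"phospho position {p} outside peptide "
                    f"[{self.peptide_start}, {end}]"
                )
        for p, q in self.per_position_probability.items():
            if not 0.0 <= q <= 1.0:
                raise FormatError(f"probability {q} at position {p} not in [0,1]")

    @property
    def peptide_end(self) -> int:
        return self.peptide_start + len(self.bare_sequence) - 1

    @property
    def is_phosphorylated(self) -> bool:
        return bool(self.phospho_positions)


@dataclass
class ParseReport:
    """Row accounting from :func:`read_evidence`."""

    n_rows: int = 0
    n_records: int = 0
    n_dropped_missing_ratio: int = 0
    n_multi_protein: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)


def parse_probability_string(s: str) -> tuple[str, dict[int, float]]:
    """Split ``'AAS(0.9)PT(0.1)K'`` into the bare sequence and a mapping
    of 1-based peptide positions to localization probabilities."""
    bare: list[str] = []
    probs: dict[int, float] = {}
    k = 0
    while k < len(s):
        if s[k] == "(":
            j = s.find(")", k)
            if j < 0 or not bare:
                raise FormatError(f"unparsable probability string: {s!r}")
            try:
                probs[len(bare)] = float(s[k + 1 : j])
            except ValueError as exc:
                raise FormatError(f"bad probability in {s!r}") from exc
            k = j + 1
        else:
            bare.append(s[k])
            k += 1
    return "".join(bare), probs


def parse_modified_sequence(s: str) -> tuple[str, list[int], set[str]]:
    """Parse ``'_AAS(ph)PT(ox)K_'`` into (bare sequence, 1-based peptide
    positions carrying a phosphate, other modification names)."""
    s = s.strip("_")
    bare: list[str] = []
    phospho: list[int] = []
    mods: set[str] = set()
    k = 0
    while k < len(s):
        if s[k] == "(":
            j = s.find(")", k)
            if j < 0:
                raise FormatError(f"unparsable modified sequence: {s!r}")
            tag = s[k + 1 : j]
            if tag == "ph":
                if not bare:
                    raise FormatError(f"phospho tag before first residue: {s!r}")
                phospho.append(len(bare))
            elif tag in _MOD_TAGS:
                mods.add(_MOD_TAGS[tag])
            else:
                raise FormatError(f"unknown modification tag {tag!r} in {s!r}")
            k = j + 1
        else:
            bare.append(s[k])
            k += 1
    return "".join(bare), phospho, mods


def _assign_positions(
    probs: dict[int, float], n_phospho: int
) -> tuple[int, ...]:
    """Pick the ``n_phospho`` highest-probability candidate positions,
    breaking ties toward the N-terminus."""
    ordered = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) < n_phospho:
        raise FormatError(
            f"{n_phospho} phosphates but only {len(ordered)} candidates"
        )
    return tuple(sorted(p for p, _ in ordered[:n_phospho]))


def _record_from_simple_row(row) -> EvidenceRecord | None:
    if pd.isna(row.ratio_hl) or row.ratio_hl == "":
        return None
    sequence = str(row.sequence)
    prob_str = "" if pd.isna(row.phospho_probs) else str(row.phospho_probs)
    n_phospho = int(row.n_phospho)
    start = int(row.start)
    pep_probs: dict[int, float] = {}
    positions: tuple[int, ...] = ()
    if prob_str:
        bare, pep_probs = parse_probability_string(prob_str)
        if bare != sequence:
            raise FormatError(
                f"probability string {prob_str!r} disagrees with sequence"
            )
        positions = tuple(
            start + p - 1 for p in _assign_positions(pep_probs, n_phospho)
        )
    elif n_phospho:
        raise FormatError("n_phospho > 0 but phospho_probs empty")
    mods = (
        frozenset()
        if pd.isna(row.other_mods) or not str(row.other_mods)
        else frozenset(str(row.other_mods).split(";"))
    )
    modified = _render_modified(sequence, [p - start + 1 for p in positions])
    return EvidenceRecord(
        protein_id=str(row.protein),
        peptide_start=start,
        bare_sequence=sequence,
        modified_sequence=modified,
        phospho_positions=positions,
        per_position_probability={start + p - 1: q for p, q in pep_probs.items()},
        other_mods=mods,
        ratio_hl=float(row.ratio_hl),
        replicate_id=str(row.replicate),
        setup_id=str(row.setup),
    )


def _render_modified(sequence: str, phospho_pep_positions: list[int]) -> str:
    marked = set(phospho_pep_positions)
    out = ["_"]
    for i, aa in enumerate(sequence, start=1):
        out.append(aa)
        if i in marked:
            out.append("(ph)")
    out.append("_")
    return "".join(out)


def read_evidence(
    path,
    dialect: str = "simple",
    drop_flagged: bool = False,
) -> tuple[list[EvidenceRecord], ParseReport]:
    """Read an evidence table; rows with a missing H/L ratio are dropped and
    counted, malformed rows are collected as row-level errors.

    ``drop_flagged`` additionally drops rows whose ``Reverse`` or
    ``Potential contaminant`` column is ``'+'`` (maxquant-like dialect only).
    """
    if dialect not in ("simple", "maxquant-like"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    report = ParseReport(n_rows=len(df))
    records: list[EvidenceRecord] = []

    if dialect == "simple":
        missing = [c for c in SIMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for idx, row in enumerate(df.itertuples(index=False)):
            try:
                if row.ratio_hl == "":
                    report.n_dropped_missing_ratio += 1
                    continue
                rec = _record_from_simple_row(row)
            except FormatError as exc:
                report.row_errors.append((idx, str(exc)))
                continue
            if rec is not None:
                records.append(rec)
    else:
        missing = [c for c in MAXQUANT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        setup_col = "Setup" if "Setup" in df.columns else None
        for idx, row in df.iterrows():
            try:
                if drop_flagged and (
                    row.get("Reverse", "") == "+"
                    or row.get("Potential contaminant", "") == "+"
                ):
                    continue
                if row["Ratio H/L"] == "":
                    report.n_dropped_missing_ratio += 1
                    continue
                proteins = str(row["Proteins"]).split(";")
                if len(proteins) > 1:
                    report.n_multi_protein += 1
                start = int(row["Start position"])
                bare, phospho_pep, mods = parse_modified_sequence(
                    str(row["Modified sequence"])
                )
                prob_str = str(row["Phospho (STY) Probabilities"])
                pep_probs: dict[int, float] = {}
                if prob_str:
                    pbare, pep_probs = parse_probability_string(prob_str)
                    if pbare != bare:
                        raise FormatError(
                            "probability string disagrees with modified sequence"
                        )
                if not pep_probs:
                    pep_probs = {p: 1.0 for p in phospho_pep}
                records.append(
                    EvidenceRecord(
                        protein_id=proteins[0],
                        peptide_start=start,
                        bare_sequence=bare,
                        modified_sequence=str(row["Modified sequence"]),
                        phospho_positions=tuple(
                            start + p - 1 for p in sorted(phospho_pep)
                        ),
                        per_position_probability={
                            start + p - 1: q for p, q in pep_probs.items()
                        },
                        other_mods=frozenset(mods),
                        ratio_hl=float(row["Ratio H/L"]),
                        replicate_id=str(row["Experiment"]),
                        setup_id=str(row[setup_col]) if setup_col else "default",
                    )
                )
            except (FormatError, ValueError) as exc:
                report.row_errors.append((int(idx), str(exc)))
    report.n_records = len(records)
    if report.n_dropped_missing_ratio:
        logger.info(
            "dropped %d rows with missing H/L ratio", report.n_dropped_missing_ratio
        )
    if report.n_multi_protein:
        logger.info(
            "kept first listed protein on %d multi-protein rows",
            report.n_multi_protein,
        )
    return records, report


def write_evidence_table(evidence: pd.DataFrame, path) -> None:
    """Write a simple-dialect evidence table (tab-delimited, UTF-8).

    Ratios are written with 17 significant digits so the log2 values survive
    the round trip bit-exactly."""
    evidence.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into {identifier: upper-case sequence};
    duplicate identifiers are a format error."""
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        proteome[rec.id] = str(rec.seq).upper()
    return proteome


def write_fasta(proteome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def sites_to_frame(sites) -> pd.DataFrame:
    """Tidy per-setup site table: one row per (site, setup)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "protein": s.protein_id,
                "positions": ";".join(str(p) for p in s.positions),
                "residues": s.residues,
                "setup": s.setup,
                "final_log2": s.final_log2,
                "n_replicates": len(s.per_replicate_log2),
                "n_evidence": s.n_evidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "positions", "residues", "setup",
            "final_log2", "n_replicates", "n_evidence",
        ],
    )


def write_site_table(sites, path) -> pd.DataFrame:
    """Write phosphosites as a wide tab-delimited table: one row per site,
    one ``ratio_<setup>`` column per setup, plus the replicate count.

    Returns the frame written; :func:`read_site_table` round-trips it.
    """
    tidy = sites_to_frame(sites)
    if tidy.empty:
        wide = pd.DataFrame(
            columns=["protein", "positions", "residues", "n_replicates"]
        )
    else:
        wide = (
            tidy.pivot_table(
                index=["protein", "positions", "residues"],
                columns="setup",
                values="final_log2",
                aggfunc="first",
            )
            .rename(columns=lambda s: f"ratio_{s}")
            .reset_index()
        )
        wide.columns.name = None
        reps = (
            tidy.groupby(["protein", "positions", "residues"])["n_replicates"]
            .sum()
            .reset_index()
        )
        wide = wide.merge(reps, on=["protein", "positions", "residues"])
        order = ["protein", "positions", "residues", "n_replicates"] + sorted(
            c for c in wide.columns if c.startswith("ratio_")
        )
        wide = wide[order].sort_values(["protein", "positions"], kind="stable")
    wide.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return wide.reset_index(drop=True)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "positions": str})
    required = {"protein", "positions", "residues"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(sorted(missing))}")
    return df
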