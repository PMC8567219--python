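"""From peptide evidence to phosphosites, phosphoislands and counter groups.

Builds a handful of evidence records on one protein by hand: two peptide
variants of the same doubly-phosphorylated site (one with a missed
cleavage), a low-confidence peptide that the 70% isoform-probability filter
discards, a second independent site, and unphosphorylated peptides that form
the islands' unphosphorylated counter groups (UCGs).
"""

from phosphoflow import (
    EvidenceRecord,
    assemble_sites,
    build_phosphoislands,
    filter_localization,
    isoform_probability,
)


def record(start, sequence, phospho, probs, ratio, replicate="r1"):
    rec = EvidenceRecord(
        protein_id="P1",
        peptide_start=start,
        bare_sequence=sequence,
        modified_sequence=f"_{sequence}_",
        phospho_positions=tuple(sorted(phospho)),
        per_position_probability=probs,
        other_mods=frozenset(),
        ratio_hl=ratio,
        replicate_id=replicate,
        setup_id="SR",
    )
    rec.log2_corrected = __import__("math").log2(ratio)  # pretend normalized
    return rec


evidence = [
    # site {12,15}: fully cleaved and missed-cleavage variants, 2 replicates
    record(10, "AASAASAK", (12, 15), {12: 0.95, 15: 0.9}, 4.0),
    record(10, "AASAASAKAAR", (12, 15), {12: 0.99, 15: 0.92}, 8.0, "r2"),
    # poorly localized: best candidate only 0.60 < 0.70 -> discarded
    record(10, "AASAASAK", (12,), {12: 0.6, 15: 0.5}, 2.0),
    # independent site {25}
    record(22, "AAASAAK", (25,), {25: 1.0}, 0.5),
    # unphosphorylated peptides: one covers {12,15}, one covers nothing
    record(10, "AASAASAK", (), {}, 1.0),
    record(40, "AAAAK", (), {}, 1.0),
]

for rec in evidence[:4]:
    print(
        f"peptide at {rec.peptide_start:>2}, sites {rec.phospho_positions}: "
        f"isoform probability = {isoform_probability(rec):.3f}"
        if rec.is_phosphorylated
        else ""
    )

retained = filter_localization(evidence, threshold=0.70)
print(f"\nretained {len(retained)} of {len(evidence)} records after the filter")

for site in assemble_sites(retained):
    print(
        f"site {site.protein_id}:{site.positions} ({site.residues}) "
        f"final log2 = {site.final_log2:+.2f} from {site.n_evidence} entries, "
        f"replicates {sorted(site.per_replicate_log2)}"
    )

for island in build_phosphoislands(retained):
    ucg = "undefined" if island.ucg_log2 is None else f"{island.ucg_log2:+.2f}"
    print(
        f"island spanning {island.span} with positions {island.positions}: "
        f"UCG log2 = {ucg} (n = {island.ucg_n})"
    )
# The two variants of {12,15} merge into one site whose final ratio is the
# mean of the replicate means; the island at {12,15} gets its UCG from the
# overlapping unphosphorylated peptide, the island at {25} has none.
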