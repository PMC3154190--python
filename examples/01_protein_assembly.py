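"""Parsimonious protein assembly on a hand-built PSM table.

Six identified spectra implicate four candidate proteins; parsimony keeps
the minimal set that explains every peptide, indistinguishable proteins
collapse into one group, and a reversed-decoy hit estimates the FDR.
"""

from speccount import PSMRecord, assemble, generate_decoy_database, remove_decoys


def psm(sid, peptide, accessions, condition):
    return PSMRecord(
        spectrum_id=sid, peptide=peptide, accessions=frozenset(accessions),
        condition=condition,
        is_decoy_map={a: a.startswith("REV_") for a in accessions},
    )


# decoys are reversed target sequences under a REV_ prefix
targets = [("ALBU", "PEPTIDEKSEQK"), ("CATB", "AAACCCK")]
print("decoy database:", generate_decoy_database(targets))

psms = [
    # ALBU and ALBU2 share identical evidence -> one indistinguishable group
    psm("s1", "PEPTIDEK", {"ALBU", "ALBU2"}, "67NR"),
    psm("s2", "SEQK", {"ALBU", "ALBU2"}, "67NR"),
    psm("s3", "PEPTIDEK", {"ALBU", "ALBU2"}, "4T1"),
    # FRAG only matches a peptide already explained by ALBU -> subsumed
    psm("s4", "SEQK", {"ALBU", "ALBU2", "FRAG"}, "4T1"),
    # CATB has its own two peptides
    psm("s5", "AAACCCK", {"CATB"}, "67NR"),
    psm("s6", "DDDEEEK", {"CATB"}, "4T1"),
    # one decoy group with two peptides
    psm("s7", "KEDITPEP", {"REV_ALBU"}, "67NR"),
    psm("s8", "KQESR", {"REV_ALBU"}, "67NR"),
]

groups, summary = assemble(psms, condition_a="67NR", condition_b="4T1")
for g in groups:
    print(
        f"group {g.representative}: members={sorted(g.members)} "
        f"peptides={g.n_peptides} counts=({g.count_A}, {g.count_B}) "
        f"decoy={g.is_decoy}"
    )
print(
    f"{summary.n_total_groups} groups, {summary.n_decoy_groups} decoy -> "
    f"FDR {summary.fdr_percent:.2f}% (doubling rule), "
    f"{len(remove_decoys(groups))} true identifications"
)
# FRAG is absent: its peptide evidence is fully explained by the ALBU group,
# so the minimal protein list does not include it.
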