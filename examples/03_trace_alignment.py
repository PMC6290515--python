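"""Compare disorder traces across aligned homologs to find deletable regions.

Aligns a disordered-terminus query with a homolog lacking that terminus,
projects both disorder traces onto the alignment columns (gap cells score
exactly 0.0) and reports the query's disordered segments with how well each
is conserved across the other rows. Segments disordered in the query but
ordered/absent elsewhere are flagged as deletion candidates for construct
design.
"""

from flexscan import (SequenceRecord, align_sequences, disorder_conservation,
                      predict_trace, project_traces)

# query: 40-residue low-complexity disordered N-terminus + ordered core;
# homolog: the ordered core alone
core = "MLVAFLIWAYVLMFAVILWFYAMLIVAFWLYVAMFILVWA" * 2
query = SequenceRecord(accession="QUERY", residues="ESPKQGSE" * 5 + core)
homolog = SequenceRecord(accession="HOM1", residues=core)

aln = align_sequences([query, homolog])
traces = [predict_trace(s, "short") for s in (query, homolog)]
matrix = project_traces(aln, traces)
_cols, segments = disorder_conservation(matrix, "QUERY", ids_threshold=0.5)

print(f"alignment: {aln.n_columns} columns, rows "
      f"{', '.join(aln.row_accessions)}")
for seg in segments:
    flag = "DELETION CANDIDATE" if seg.deletion_candidate else "conserved"
    print(f"query residues {seg.start}-{seg.end}: mean disorder "
          f"{seg.mean_score:.2f}, disordered in {seg.cross_row_fraction:.0%} "
          f"of other rows -> {flag}")
print("\nA flagged segment is disordered in the query but not in its "
      "homologs: truncating it from the expression construct is unlikely "
      "to remove conserved function.")
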