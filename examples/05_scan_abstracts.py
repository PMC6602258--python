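"""Scan raw abstract text against filtered name dictionaries.

Dictionaries map stable identifiers to surface names; filtering removes
names shorter than three characters and names that are common English
words (which would otherwise flood the counts with false positives),
while keeping the identifiers themselves stable.
"""

from golink import (
    TermDictionary,
    default_stopwords,
    filter_dictionary,
    scan_corpus,
    tally_counts,
)

genes = TermDictionary("gene", {
    "BRCA1": {"BRCA1", "breast cancer 1"},
    "IL6": {"IL", "interleukin 6"},          # "IL" is too short to keep
})
gos = TermDictionary("go", {
    "GO:0006915": {"apoptosis"},
    "GO:0007612": {"learning"},              # a common English word
})

genes_f = filter_dictionary(genes, default_stopwords())
gos_f = filter_dictionary(gos, default_stopwords())
print("surviving gene names:", {k: sorted(v) for k, v in genes_f.entries.items()})
print("surviving GO names:  ", {k: sorted(v) for k, v in gos_f.entries.items()})

abstracts = [
    ("A1", "BRCA1-mediated apoptosis in mammary cells."),
    ("A2", "Interleukin 6 levels correlate with learning performance."),
    ("A3", "No relevant terms appear in this abstract."),
]
records = scan_corpus(abstracts, genes_f, gos_f)
for rec in records:
    print(f"{rec.abstract_id}: genes={sorted(rec.genes)} gos={sorted(rec.gos)}")

counts = tally_counts(records)
print(f"n_total = {counts.n_total} (A3 mentions nothing and is not counted)")
print("GO:0007612 kept its identifier but matches nothing after filtering.")
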