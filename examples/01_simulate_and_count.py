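"""Simulate a planted-module literature corpus and tally co-occurrences.

The generator plants four functional modules: each module's abstracts
discuss one focal gene together with the module's shared GO vocabulary,
while direct gene-gene co-mentions stay rare.  The tally below is the
sufficient statistic for everything downstream.
"""

from golink import SyntheticCorpusConfig, simulate_corpus, tally_counts

cfg = SyntheticCorpusConfig(seed=0)  # 40 genes, 80 GO terms, 2000 abstracts
records, truth = simulate_corpus(cfg)
counts = tally_counts(records)

print(f"abstracts simulated:            {len(records)}")
print(f"abstracts with >=1 mention:     {counts.n_total}   (this is n_total)")
print(f"genes seen / GO terms seen:     {len(counts.n_gene)} / {len(counts.n_go)}")
print(f"gene-GO pairs co-mentioned:     {len(counts.n_joint)}")
print(f"gene-gene pairs co-mentioned:   {len(counts.n_gene_joint)}")

g = truth.module_genes(0)[0]
t = truth.module_gos(0)[0]
print(f"\nmodule-0 gene {g}: mentioned in {counts.n_gene[g]} abstracts")
print(f"module-0 term {t}: mentioned in {counts.n_go[t]} abstracts")
print(f"their joint count: {counts.n_joint.get((g, t), 0)} "
      "(far above chance -> a strong association signal)")
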