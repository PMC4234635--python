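"""Find functional terms over-represented among differentially expressed genes.

Simulates an experiment whose term table contains two planted enriched
terms, then tests every term with the upper-tail hypergeometric law
against the annotated-gene background and prints the top of the ranking.
The planted terms should surface with tiny q-values; background terms
should hover near q = 1.
"""

from tagdge import SimulationConfig, call_degs, enrich_terms, simulate_pair, simulate_terms

config = SimulationConfig(seed=7)  # 5,000 genes, 5% DE, 50 terms, 2 planted
pair, truth = simulate_pair(config)
assignments, planted = simulate_terms(truth, config)

deg_ids = {r.gene_id for r in call_degs(pair) if r.status != "ns"}
records = enrich_terms(deg_ids, assignments, namespace="GO")

print(f"universe: N={records[0].N} annotated genes, n={records[0].n} DEGs among them")
print(f"planted terms: {', '.join(planted)}\n")
print("term        m/M        p-value     q-value   enriched")
for r in records[:6]:
    print(f"{r.term_id}  {r.m:3d}/{r.M:<3d}   {r.p_value:10.3e}  {r.q_value:.3e}  {r.enriched}")
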