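"""Signature-reversal perturbagen screening with MoA and target follow-up.

Queries a 200-perturbagen signature library with the resistance expression
program, ranks compounds by predicted reversal, and summarizes the hits'
mechanisms of action and gene targets.
"""

import warnings

import broadres as br

warnings.filterwarnings("ignore")

bundle = br.simulate_panel(br.SimulationConfig(seed=1))
truth = bundle.truth

out = br.reversal_screen(
    set(truth.true_signature_up),
    set(truth.true_signature_down),
    bundle.signatures,
    top_k=100,
)
top = out.iloc[0]
(reverser,) = truth.true_reverser_ids
print(
    f"top-ranked perturbagen: {top.perturbagen_id} "
    f"(combined score {top.combined_score:.1f}, q = {top.q_value:.2e})"
)
print(f"planted reverser was {reverser} -> recovered: {top.perturbagen_id == reverser}")

hits = set(out.loc[out.is_hit, "perturbagen_id"])
moa = br.moa_enrichment(hits, bundle.signatures)
print(f"most enriched mechanism among the top-100 hits: {moa.iloc[0].set_name} "
      f"(q = {moa.iloc[0].q_value:.2f})")

tally = br.target_tally(hits, bundle.signatures)
print("most frequently targeted genes among hits:")
print(tally.head(5).to_string(index=False))
print("(ranking is driven by the overlap between each compound's down-signature")
print(" and the genes over-expressed in resistant lines)")
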