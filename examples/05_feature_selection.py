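"""Majority-voting feature selection.

First tallies the frozen reference vote matrix (seven methods voting on the
26 cluster features), then re-runs the seven scoring methods on a synthetic
feature table with planted grade structure.
"""

from nucleiclust import build_vote_matrix, load_reference_votes, tally_votes
from nucleiclust.synthdata import default_class_means, generate_feature_table

votes = load_reference_votes()
selected, rejected = tally_votes(votes, min_votes=4)
print(f"reference vote matrix: {len(selected)} selected / {len(rejected)} rejected "
      f"at min_votes=4")
print(f"top row: '{votes.index[0]}' with {votes['votes'].iloc[0]} of 7 votes")

means, sds = default_class_means(effect_size=2.0)
table, labels = generate_feature_table(40, means, sds, seed=0)
fresh = build_vote_matrix(table, labels, k_select=16, min_votes=4, seed=0)
fresh_selected, _ = tally_votes(fresh, min_votes=4)
print(f"\nre-scored on a synthetic 3-grade table: {len(fresh_selected)} features "
      f"reach 4+ votes")
print(fresh[["votes", "decision"]].head(8).to_string())
print("-> filters (chi-square, Fisher, information gain, ANOVA) and wrappers")
print("   (RFE, permutation importance, Boruta) each cast one vote per feature.")
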