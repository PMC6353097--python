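"""Recover a circular permutation with the CSA global search.

A 60-residue self-avoiding walk and a copy with its two halves swapped
in chain order (coordinates untouched).  A sequential aligner could
match at most one half; the non-sequential search recovers the full
correspondence as two forward blocks, with recall 1.0 against the
generator's ground truth.
"""

import nsalign as ns

A = ns.make_synthetic_chain("walk", 60, seed=6)
B, truth = ns.make_permuted_pair(
    A, [(30, 60, "forward"), (0, 30, "forward")], noise_sigma=0.0, seed=9
)

config = ns.CSAConfig(bank_size=10, n_seeds_per_round=6, n_trials_per_seed=4,
                      n_collect=60, seed_budget=80, rng_seed=8)
bank = ns.csa_search(A, B, ns.ScoreSpec(function="tm"),
                     ns.Constraints(min_block_size=4, allow_reverse=True), config)

best = bank.best[0]
s = ns.summarize(best, A, B)
precision, recall = ns.precision_recall(best, truth)
print(f"best TM = {bank.best_score:.4f} after {bank.n_generated} refined trials")
print(f"n = {s.n}, rmsd = {s.rmsd:.3f} Å, blocks = {s.block_sizes}")
print(f"precision = {precision:.2f}, recall = {recall:.2f} vs ground truth")
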