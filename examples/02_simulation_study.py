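"""Perturbation ramp: how matching degrades and how the threshold protects it.

Generates a clone-pair cohort, perturbs one member of each pair at
increasing levels, and matches with no threshold and with threshold 7.
Without a threshold everything gets paired, so total GD grows and a few
pairs are misassigned at high perturbation; with threshold 7 genetically
heterogeneous candidates are refused, trading unpaired individuals for
zero misassignment through the 11% level.
"""

from admixpair import MatchConfig, evaluate_solution, generate_base, pam_simple, perturb

N_PAIRS = 250
base = generate_base(N_PAIRS, K=9, seed=4)

print(f"{'x':>5} | {'mis':>4} {'GD':>8} {'unpaired':>8} | {'mis':>4} {'GD':>8} {'unpaired':>8}")
print(f"{'':>5} | {'no threshold':^22} | {'threshold 7':^22}")
for x in (0.0, 0.05, 0.08, 0.11, 0.14, 0.20):
    ds = perturb(base, x)
    plain = evaluate_solution(pam_simple(ds.cohort), ds.truth)
    strict = evaluate_solution(
        pam_simple(ds.cohort, MatchConfig(threshold=7)), ds.truth
    )
    print(
        f"{x:5.2f} | {plain.n_misassigned:4d} {plain.total_gd:8.4f} "
        f"{plain.n_unpaired:8d} | {strict.n_misassigned:4d} "
        f"{strict.total_gd:8.4f} {strict.n_unpaired:8d}"
    )
print(
    "\nGD rises with perturbation; the threshold keeps accepted pairs\n"
    "homogeneous (low GD, 0 misassigned) at the cost of unpaired individuals."
)
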