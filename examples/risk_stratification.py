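"""Two-stage sequential Bayesian risk stratification.

Starting from a 40% pretest probability of moderate/severe negative
symptoms, a clinical assessment (SE 0.47, SP 0.89) followed by an
MRI-gyrification signature (SE 0.61, SP 0.64) stratifies individuals into
risk groups by chained Bayes updating.  NNT uses an illustrative
intervention risk ratio of 0.15, which reproduces the 1 / 2-3 / 6 NNT
ladder of the published two-test scenario.
"""

from negprog import DiagnosticTest, build_tree

tree = build_tree(
    pretest=0.40,
    tests=[
        DiagnosticTest("clinical", sensitivity=0.47, specificity=0.89),
        DiagnosticTest("gyrification", sensitivity=0.61, specificity=0.64),
    ],
    rr=0.15,
)

print(tree.to_frame().to_string(index=False))
print()
for leaf in tree.leaves:
    path = "".join(leaf.result_path)
    print(
        f"tests {path}: posttest {100 * leaf.posttest_p:5.1f}%  "
        f"({leaf.category}-risk, {100 * leaf.branch_mass:4.1f}% of subjects, "
        f"NNT {leaf.nnt_rounded})"
    )
# Reading: two positive tests push the outcome probability from 40% to 83%
# (high risk, NNT 1); two negatives lower it to 19% (low risk, NNT 6).  The
# branch masses sum to 1 and their probability-weighted posttest values
# return the 40% pretest exactly.
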