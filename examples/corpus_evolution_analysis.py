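"""Full evolution analysis of a synthetic versioned corpus.

Generates a base ontology and five successor versions with known mutations
(classes added/deleted, annotations edited, restrictions added), writes them
as an OWL corpus, and runs the complete pipeline: raw metrics, static and
dynamic scores, change statistics, accumulative profile, Wilcoxon ranking of
version pairs and the activity/quality PCA.
"""

import tempfile
from pathlib import Path

from oquare import GeneratorParams, MutationPlan, generate_corpus, write_corpus
from oquare.pipeline import analyse_corpus

params = GeneratorParams(n_classes=50, depth=5, seed=42)
plans = [
    MutationPlan(operations={"add_class": 4, "edit_annotation": 5}, seed=1),
    MutationPlan(operations={"delete_class": 3, "add_restriction": 4}, seed=2),
    MutationPlan(operations={"add_class": 2, "deprecate_class": 2}, seed=3),
    MutationPlan(operations={"edit_annotation": 8, "add_restriction": 2}, seed=4),
    MutationPlan(operations={"add_class": 6, "delete_class": 1}, seed=5),
]
graphs, deltas, _ = generate_corpus(params, plans)

with tempfile.TemporaryDirectory() as tmp:
    write_corpus(graphs, tmp)
    result = analyse_corpus(tmp, normalise=False)

print("change statistics under the dynamic scale")
print("(magnitude = % of metrics whose score moved; mean = net direction):")
for version, st in result.change_stats["dynamic"]:
    fwd = "-" if st.forward_mean is None else f"{st.forward_mean:.2f}"
    back = "-" if st.backward_mean is None else f"{st.backward_mean:.2f}"
    print(
        f"  {version}: magnitude {st.magnitude:5.1f} %  mean {st.mean_change:+.2f} "
        f"(forward {fwd}, backward {back})"
    )

print("\naccumulative mean-change profile (running quality trend):")
print("  " + ", ".join(f"{v:+.2f}" for v in result.profiles["dynamic"]))

print("\nversion pairs ranked by raw-metric change (Wilcoxon signed-rank):")
for r in result.wilcoxon:
    p = "degenerate" if r.p_value is None else f"p={r.p_value:.2e}"
    print(f"  {r.version}: median |change| = {r.estimate:.4f} ({p})")

if result.pca is not None:
    print("\nPCA of change statistics vs editorial activity (first two factors,")
    print(f"explained variance {[round(v, 2) for v in result.pca.explained_variance]}):")
    for name, row in zip(result.pca.variables, result.pca.loadings):
        print(f"  {name:24s} {row[0]:+.2f}  {row[1]:+.2f}")
    print(
        "\nVariables with same-signed large loadings on a factor co-varied "
        "across versions; with only five pairs the factors are noisy — on "
        "real corpora with more releases they separate editorial activity "
        "from quality movement."
    )
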