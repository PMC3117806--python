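"""Generate a synthetic gold-annotated corpus and score noisy annotators.

A paragraph is built from one sentence template per sampled action
family; simulated annotators perturb the gold spans (boundary jitter,
label confusion, drops).  The pairwise agreement matrix shows the metric
ordering: alignment-based agreement tolerates the boundary noise that
sinks exact matching.
"""

from chemphrase import evaluation as ev
from chemphrase.fixtures import GenerationConfig, simulate_annotators
from chemphrase.pipeline import parse_document

config = GenerationConfig(
    seed=42,
    n_sentences=40,
    boundary_jitter_tokens=2,
    label_confusion_prob=0.1,
    drop_prob=0.05,
)
fixture, gold, annotators = simulate_annotators(config, n_annotators=4)

print("first two generated sentences:")
for sentence in fixture.sentences[:2]:
    print("  " + sentence)

doc = parse_document(fixture.text)
recovered = [a.type.name for a in doc.actions]
hits = sum(g == r for g, r in zip(fixture.labels, recovered))
print(f"\npipeline recovered {hits}/{len(fixture.labels)} gold action labels")

for name, metric in [
    ("exact", lambda a, b: 100 * ev.dice(a.spans, b.spans, ev.exact_match)),
    ("filtered", lambda a, b: 100 * ev.dice(a.spans, b.spans, ev.filtered_match)),
    ("aligned", ev.aligned_agreement),
]:
    report = ev.agreement_matrix(annotators, gold, metric)
    print(
        f"{name:9s} gold-annotator mean {report.machine_annotator_mean:5.1f}%  "
        f"inter-annotator mean {report.inter_annotator_mean:5.1f}%"
    )
# Aligned >= filtered >= exact: the alignment pairs jittered spans that
# string comparison treats as disjoint annotations.
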