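# Methods

## Problem and model

`cellprompt` treats cell type annotation as a text-completion task: each
cluster of an scRNA-seq experiment is represented by its top differential
genes, and a language model is asked to name one cell type per row. The
package's job is to make that interaction deterministic and auditable
(prompt grammar, conversation provenance, transcript replay) and to quantify
annotation quality (agreement, simulation benchmarks, reproducibility). It
deliberately contains no clustering, normalisation or differential testing —
the input contract is an exported differential-gene table — and no ontology
or embedding-based label matching: semantic equivalence of free-text labels
is a human judgment that the package records but never infers.

## Marker extraction

Per cluster, records are sorted by ascending p-value; ties break by larger
absolute log fold change (absent = 0), then lexicographic gene symbol, making
output identical across platforms. The first *k* distinct symbols form the
cluster's marker row (duplicates keep the best-ranked occurrence; a gene
repeated in a prompt row carries no information). A p-value of exactly 0 is
accepted and sorts first, as commonly produced by exported tables. Cluster
order is order of first appearance in the file, matching what the analyst
sees in their own export. Gene symbols are case-preserved since mouse symbols
are mixed-case. Default *k* = 10.

## Prompt grammar

The rendered prompt is: two-sentence header naming the species and tissue,
optional mixture clause, optional unknown clause (in that fixed order,
between header and rows), then one marker row per line. All wording lives in
a versioned template registry (`templates/default.yaml`) so a prompt set can
be pinned or swapped without code changes. When the tissue string is empty
(atlas-wide annotation aggregated over tissues), the header collapses to
"... of human cells ..." — the single defined variant for that case. The
refinement turn is the exact string `Be more specific`, applied to all rows
at once in the same conversation; the vector-conversion turn asks for a
`c('...')` R expression.

Response parsing is conservative plumbing: split on newlines, drop blanks,
strip enumeration tokens and anything up to a line's last colon (chat models
sometimes echo `Row 1:` or the gene list), strip one trailing period, and
require exactly one label per row — any count mismatch is an error carrying
the raw text, never a silent truncation.

## Backends

The backend contract is a pure function from an alternating user/assistant
conversation to assistant text. Three implementations:

- **mock dictionary** — scores each row against a dictionary of cell types,
  per type as |row ∩ markers| / |markers| (normalising by the type's own
  marker-set size so a long row containing all of a small type's markers
  still matches strongly). Best scorer wins, ties lexicographic; zero overlap
  everywhere yields the unknown label; when the best type and the best
  *disjoint* second type both reach the mixture threshold (default 0.5 of
  each type's own markers), a mixture of the two is emitted. This is a test
  oracle: deterministic and sensible, not a biological annotator.
- **transcript** — replays a JSON Lines store keyed by a SHA-256 digest of
  the rendered conversation; a miss is an error naming the digest, and
  re-recording a digest with different text is refused.
- **live** — a chat-completions adapter (stdlib HTTP) reading its credential
  from an environment variable. It is excluded from the test suite; the
  original annotations were obtained through a chat interface whose sampling
  settings are unknown, so no default here can claim fidelity to them.

Responses are cached on (digest, model, temperature); a temperature above 0
marks the backend stochastic and disables caching. All clusters of a tissue
go into one prompt by default; `max_rows_per_prompt` splits oversized inputs
with deterministic reassembly.

## Evaluation

Agreement is three-level (1 / 0.5 / 0 for fully / partially / mismatch);
group summaries report the level proportions and the unweighted mean score,
which satisfies mean = p_fully + 0.5·p_partially to 1e-12 by construction.
Averages weight each cell type once. The reproducibility statistic normalises
labels by trim + case-fold + whitespace-collapse only — deliberately no
singular/plural stemming, since surface-distinct labels such as "endothelial
cells" vs "blood vascular endothelial cells" must count as different — and
reports modal_count/n per cell type (ties lexicographic) with an unweighted
mean. Displayed values round half-up to 2 decimals; raw fractions stay in the
data structures.

## Simulation design

Both benchmarks follow a 10 positives + 10 negative controls per iteration,
5 iterations design. Mixed rows are the deduplicated union of two uniformly
sampled distinct types' marker lists (first parent's order, then the second's
novel genes); negative-control types are sampled without replacement within
an iteration, and queries are shuffled within each iteration so positives and
negatives interleave. Unknown rows draw 10 genes without replacement from a
gene universe. Response classification is by configurable keyword lists
(defaults: "mixture"/"mixed" or two names joined by and, `/`, `+`; and
"unknown"/"novel"/"unidentified"/"not a known") because the original
correctness call was made by a human reader; the rule is logged with results.
A mixed-truth query answered with exactly one parent type is counted
incorrect but reported separately (`parent_only_ids`), since that judgment is
debatable. Accuracy is reported both as the unweighted mean of per-iteration
accuracies and pooled per query, as the two can differ.

## Synthetic fixtures

The fixtures module ships a curated dictionary of 12 human breast cell types
(immune, stromal, epithelial) with 10 marker genes each, chosen so no gene
appears under two types: disjointness makes the mock's overlap scoring
unambiguous, so closed-loop accuracy of exactly 1.0 is the designed sanity
bound of the pipeline, not an empirical claim about any model. Real gene
symbols are used for readability, but the lists are a synthetic test
dictionary, not a vetted literature resource. The synthetic gene universe
uses a reserved symbol prefix, guaranteeing disjointness from every marker —
which is what real random genome draws approximate but do not guarantee. The
decoy differential table gives each cluster its true markers at the smallest
p-values and then ranks 11..10+n filled with other types' markers; because
rows at larger *k* are supersets of rows at smaller *k* and the true type
always scores 1.0 under the mock, per-cluster correctness is monotone
non-increasing in *k*, which is the qualitative degradation the top-k sweep
demonstrates. What these fixtures do **not** emulate: noisy or shared markers
between real cell types, model hallucination, label synonymy, or prompt
sensitivity of a real LLM — passing tests certify the apparatus, not any
model's biology.

## Problem sizes and numerics

Default study sizes (10+10 × 5 reps, 12 cell types, 200-gene universe,
decoy sweep at k ∈ {10, 20, 30, 50}) run in seconds; the acceptance script
uses exactly these sizes. Proportions are exact rational arithmetic over
small counts, so the only tolerance anywhere is 1e-12 on the agreement
identity. Seeds: every generator takes an explicit seed or numpy Generator;
the acceptance script derives sub-seeds from its single `--seed` via
`SeedSequence`.

## Known limitations

- The mock's mixture rule requires the two parents' dictionary marker sets to
  be disjoint; with heavily overlapping real marker sets it under-calls
  mixtures (by design — it keeps the oracle unambiguous).
- The keyword classifier can misread exotic label phrasings (e.g. a genuine
  cell type name containing "and"); the lists are configurable per call.
- Reproducibility treats surface-distinct synonyms as different labels, so it
  is a lower bound on semantic reproducibility.
- The live adapter's fidelity to any historical chat-model run is unknowable
  and not claimed.
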