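# xfakesci

Network-driven detection of machine-generated pseudo-scientific abstracts.

Large language models can emit fluent, PubMed-styled abstracts that are hard
to tell from genuine publications. This package implements a lightweight,
interpretable detector for that problem, aimed at editors, integrity teams
and text-forensics researchers: instead of training a deep classifier, it
summarises each class of text by the *structure of its word co-occurrence
network* and by how strongly new documents re-use that structure.

## The method

For each class *c* (genuine publications vs generated text), from its first
`n_train` documents:

1. **Bigram features.** Abstracts are lowercased, sentence-tokenized and
   stripped of stopwords; consecutive word pairs (bigrams) *t* are scored
   with TF-IDF:

   tf(t, d) = count of t in d / total bigrams in d
   idf(t, D) = ln( N / (1 + df(t, D)) )
   tf-idf(t, d, D) = tf(t, d) · idf(t, D)

   where N is the number of documents and df the number containing *t*.
   Bigrams seen in fewer than `min_df` documents are dropped.

2. **Term graph and LCC.** Each retained bigram (w₁, w₂) contributes nodes
   w₁, w₂ and an undirected edge {w₁, w₂}. The graph is pruned to its
   **largest connected component (LCC)** — the trained model of the class.
   Generated text characteristically yields fewer nodes but more edges
   (a lower node:edge ratio) than publication text.

3. **Calibration.** The remaining documents are chunked into sequential
   folds of `fold_size`. For each document, the **bigram-contribution
   ratio** is the number of its bigram occurrences whose edge lies in the
   class LCC, divided by its word count. The min and max of the fold means
   give the class a calibration band [lower, upper].

A test document gets one ratio ("point") per class. If exactly one class's
band contains its point, that class wins. If neither does, the label goes
to the class with the smaller **proximity distance**

distance = min(|point − upper|, |point − lower|),

and exact ties fall back to the publication label (conservative: never flag
real science on a coin flip). Evaluation fixes the publication class as
positive and reports F1 = 2·TP / (2·TP + FP + FN).

Because no corpus of generated abstracts can be downloaded here, the
package ships a deterministic synthetic-corpus generator whose two classes
differ in vocabulary breadth, stock-phrase reuse and Zipf skew — the same
statistics the detector keys on — so the entire pipeline is testable
offline (see `docs/methods.md`).

## Worked example

```python
from xfakesci import (SynthConfig, XFakeSciClassifier, confusion_matrix,
                      generate_paired_corpora)

cfg = SynthConfig(seed=13)            # 750 docs/class: 100 train + 6 folds + 50 test
pub, gen = generate_paired_corpora(cfg)
pub, gen = list(pub), list(gen)

n_fit = 700
clf = XFakeSciClassifier(n_train=100, fold_size=100)
clf.fit([a.abstract for a in pub[:n_fit]] + [a.abstract for a in gen[:n_fit]],
        ["PUBMED"] * n_fit + ["GPT"] * n_fit)

for cls in clf.classes_:
    m, r = clf.models_[cls], clf.ranges_[cls]
    print(f"{cls}: {m.n_nodes} nodes, {m.n_edges} edges, "
          f"band [{r.lower:.3f}, {r.upper:.3f}] from {r.n_folds} folds")

X_test = [a.abstract for a in pub[n_fit:]] + [a.abstract for a in gen[n_fit:]]
y_test = ["PUBMED"] * 50 + ["GPT"] * 50
rep = confusion_matrix([str(p) for p in clf.predict(X_test)], y_test)
print(f"TP={rep.TP} FP={rep.FP} FN={rep.FN} TN={rep.TN}  F1={rep.f1_percent:.2f}%")
```

prints

```
GPT: 596 nodes, 1550 edges, band [0.279, 0.291] from 6 folds
PUBMED: 862 nodes, 1069 edges, band [0.131, 0.142] from 6 folds
TP=50 FP=0 FN=0 TN=50  F1=100.00%
```

The generated-like model has fewer nodes but many more edges than the
publication-like model (node:edge ratio 0.38 vs 0.81), and the two
calibration bands are widely separated — exactly the signature the
classifier exploits. All 50 publication abstracts and all 50 generated
documents of the held-out mix are labelled correctly here; across seeds
the publication-class F1 stays above 90%.

A command-line interface mirrors the pipeline stages:

```bash
xfakesci synth --seed 13 --out-pub pub.jsonl --out-gen gen.jsonl
xfakesci train --pub pub.jsonl --gen gen.jsonl --out-models models --out-ranges ranges.json
xfakesci classify --models models/pubmed.lcc,models/gpt.lcc \
                  --ranges ranges.json --in gen.jsonl --out preds.jsonl
xfakesci benchmark --train train.jsonl --test test.jsonl --seed 13 --out bench.json
```

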