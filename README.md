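# seqrecode

Does learning a sequence *strengthen* its initial neural code, or
*replace* it?  Two classic accounts of sequence learning make opposite
predictions about the similarity between novel and well-learned
sequences.  Under **associative learning**, a sequence is a set of
item–position bindings and repetition only sharpens them: learned and
novel sequences share one code, and learned patterns should be the
*less noisy* half of it.  Under **recoding**, repetition re-encodes a
sequence into chunks: a learned four-item sequence becomes a single
chunk code with no overlap with the item codes of novel sequences.

`seqrecode` implements the full model-comparison pipeline for a
four-item sequence-recall design — for methodologists who want to
stress-test the logic, and for anyone building a similar experiment:

- sequence representation models and their RDMs: item–position
  (Hamming distance), item–item (shared adjacent n-grams,
  `D = 1 − γ·|Cᵢ ∩ Cⱼ|`), and a recency-weighted item-mixture null;
- a Bayesian chunk-learning model: an inventory of n-grams with
  combinatorial priors `p(c) ∝ (n−k)!/n!`, parse-based encodings with
  link probability η, model evidence
  `log p(x,z) = Σ_c log p(c) + Σ_tokens F·log η`, and an optimal-model
  search whose fitted encoding is stationary over the experiment
  (repeating trial → one four-gram, novel trial → four item codes);
- constraint-based experimental design (Monte-Carlo search maximising
  pairwise-distance entropy) and randomised trial schedules;
- RSA with Spearman fits, leave-one-out noise ceilings, and
  permutation/bootstrap group inference, including the cross-condition
  test of the associative noise-reduction prediction;
- model-free cosine-distance trajectories with slope tests;
- the combinatorial capacity/interference analysis of the two codes;
- a synthetic voxel-pattern cohort generator with known ground truth,
  so every stage is testable end to end without any scanner data.

## Worked example

```python
import seqrecode as sq

# the two learned sequences, practised 12 times each
practice = ["CADB"] * 12 + ["DCBA"] * 12
print(sq.reference_models(practice)[["model_id", "log_code", "log_encoding", "log_total"]])
#   model_id   log_code  log_encoding   log_total
# 0   4-gram  -9.128696    -55.262042  -64.390739
# 1   2-gram -15.484804   -110.524084 -126.008889
# 2   1-gram -11.090355   -221.048169 -232.138524

model = sq.fit_optimal_model(practice + ["ABCD"])
print(["".join(c) for c in model.chunks])
# ['A', 'B', 'C', 'D', 'CADB', 'DCBA']
```

The first table is the code/encoding trade-off after practice: the
4-gram model pays the largest one-off code cost (−9.13 = 2·log 1/96)
but by far the cheapest per-trial encodings (one link instead of two or
four), so it wins on evidence — the learned sequences are chunked.
Adding a single novel sequence leaves the two learned chunks in place
and encodes the newcomer with the four item codes: the learning model
predicts a *representational split* between repeating and novel trials.

The capacity argument, in two lines:

```python
hist = sq.shared_code_histogram("item-position", "ABCD")
print({k: f"{p:.1%}" for k, p in enumerate(hist.proportions)})
# {0: '31.6%', 1: '42.2%', 2: '21.1%', 3: '4.7%', 4: '0.4%'}
```

A random four-item sequence shares two of its four item–position codes
with 21% of all 256 possible sequences and at least one with 68% —
after learning about five sequences this way, no unaffected sequence
remains (`sq.capacity_curve`), whereas the bi-gram chunk code leaves a
strictly larger pool untouched at every step.

## Analysis pipeline

The numbered drivers under `analysis/` run the complete study on
synthetic cohorts and write tables under `results/` (large regenerable
cohorts go to `scratch/`):

```bash
python analysis/01_generate_design.py      # sequence set + schedule
python analysis/02_chunking_models.py      # evidence tables, stationarity
python analysis/03_interference.py         # Fig-style capacity tables
python analysis/04_simulate_cohorts.py     # 22-subject cohorts per scenario
python analysis/05_rsa_model_comparison.py # group RSA + associative test
python analysis/06_pattern_dynamics.py     # distance-trajectory slopes
```

A typical `05` output line, on a cohort generated under chunk-recoding
ground truth:

```
chunk: best model chunk (r = 0.219, p = 0.0001, ceiling 0.16-0.30); associative test: no-correlation
```

i.e. the chunk RDM wins the group fit and the associative
noise-reduction test correctly finds nothing — while on the
associative-ground-truth cohort the same line reads
`best model item-position ... associative test: repeating-less-noisy`.

There is also a thin CLI (`seqrecode design|interference|run-all
--config cfg.yaml --out dir`) for config-driven smoke runs with a
checksummed manifest.

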