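# Methods

## The problem

A set of N clients each hold a private labeled dataset D_l^i (for example
per-hospital patient records) and want to train a shared classifier
without revealing anything about their data beyond a strict local
differential privacy (LDP) guarantee. Classical federated averaging
exchanges model parameter updates; protecting those with LDP noise scaled
to their dimensionality destroys utility. This package implements the
alternative simulated here: clients reveal only *predictions on a handful
of public, unlabeled samples*, perturbed by randomized response, and the
server distills those votes into the global model.

## The mechanism

**Randomized response.** A client's answer on one public sample is a
one-hot class vote y ∈ {0,1}^C. The channel keeps y with probability β
and otherwise replaces it with a one-hot drawn uniformly over all C
classes (the original class included), so

    Pr[out = y] = β + (1−β)/C,   Pr[out = y′] = (1−β)/C  (y′ ≠ y).

The worst-case log-likelihood ratio between any two inputs is
ln(1 + βC/(1−β)); `verify_ldp` computes it by exhaustively enumerating
all (input, input, output) triples of the channel rather than trusting
the closed form, and is used as the oracle in tests.

**Budget allocation.** A round in which each client answers K samples
composes K independent channel uses. Splitting the round budget ε evenly,
per-answer (ε/K)-LDP is realized exactly by

    β = (e^{ε/K} − 1) / (e^{ε/K} − 1 + C).

We report per-round ε only; budget accumulation across rounds is
documented, not mitigated (multi-round amortization schemes such as model
shuffling are out of scope).

**Debiasing.** With uploads ŷ_c from the participating group G_t, the
server computes

    (1/β) · ( mean_c ŷ_c − (1−β)/C · 1 ),

an unbiased estimator of the mean clean vote whose MSE decays as
1/(β²|G_t|). Entries can be negative; the raw estimate is stored for
audit and a clip-to-zero renormalization is used as the training target.

**Active selection and self-training.** The server scores every pool
sample by the predictive entropy u_i of the current global model.
Knowledge-transfer (KT) samples are drawn without replacement with
probabilities softmax(u) (uncertain samples carry the most information);
self-training samples with probabilities softmax(−u) (confident samples
make reliable pseudo-labels). Round 1 uses a uniform draw since the model
is uninformative. Softmaxes are computed with max-subtraction; ties are
broken by the draw itself.

**Knowledge buffer.** Debiased targets are kept in a FIFO buffer of B
records (not rounds — capacity is independent of K; default B = 10·K).
Each round the global model is fine-tuned on everything buffered with
soft-target cross-entropy, then self-trained on M argmax pseudo-labels.

## Synthetic task

The generator draws a class-conditional Gaussian mixture with unit
covariance. Class means are √2·separation times hyperoctahedron vertices
(±e_i), so the minimum distance between two class means is 2·separation:
`separation` is the half-margin between nearest classes in noise-σ units.
`separation=0` collapses every mean to the origin (chance-level task);
`separation=3` (the default) gives a Bayes accuracy near 0.99 that a
linear model reaches from ~100 training samples. For C > 2d, mean
directions fall back to seeded random unit vectors.

What this emulates: a well-posed C-class task with controllable
difficulty, partitioned non-IID across clients. What it does not emulate:
feature correlation structure, label noise, class imbalance in the global
distribution, and the representation-learning burden of image/text data.
Passing tests therefore demonstrate correctness of the mechanisms and
their interaction, not performance claims about real modalities.

Client partitions: `iid` (round-robin after shuffle), `class_noniid`
(per-class client shares drawn from Dirichlet(α), default α = 0.5),
`size_noniid` (client sizes from log-normal(0, σ), default σ = 1),
`mixed_noniid` (both composed). Draws that leave a shard empty are
retried with fresh randomness up to 25 times. 20% of the training data is
split off as the unlabeled public pool before partitioning; its labels
are discarded permanently and the pool type carries no label field, so no
server code path can consult them. The pool is drawn uniformly (not
class-balanced); a class-balanced pool is a plausible alternative we did
not adopt.

## Default study conditions

n = 2000 training samples (pool 400, private 1600), C = 10, d = 8,
separation = 3, N = 10 clients, class-non-IID partition, T = 30 rounds,
ε = 5, K = 2, B = 20, test set 2000 samples. These sizes keep a full run
under ~4 s so replicated comparisons and ablations are cheap.

## Training schedule and model

The reference model behind the classifier handle is a one-hidden-layer
tanh network (hidden = 32, Xavier-style init) trained by minibatch SGD
(batch 32) on soft-target cross-entropy; `hidden=0` gives plain
multinomial logistic regression. The nonconvex default is deliberate: a
convex logistic model never forgets between rounds, which removes the
very failure mode the knowledge buffer and self-training exist to fix —
with `hidden=0` both mechanisms measure as useless, with a hidden layer
both measurably help.

Defaults: 5 local epochs per client per round, lr 0.05, full client
participation, 20 server fine-tune epochs per round, M = 5 self-training
samples, 1 self-training epoch. These were chosen by pilot simulation at
the default conditions: at ε = 5, C = 10 and |G_t| participating clients,
the per-target standard deviation of the debiased estimate scales as
1/(β√|G_t|), and with half participation (|G_t| = 5) or single-epoch
local training, target argmax noise is large enough that self-training
amplifies errors and buffer fine-tuning re-fits noise; the distillation
loop then never ignites. Deeper server fine-tuning (≥25 epochs) makes
the buffer's measured contribution larger but turns self-training's
contribution negative — the two rehearsal mechanisms compete. The default
of 20 is the schedule at which every mechanism contributes positively.

## Known limitations

- At this scale the largest measured ablation drop is usually the
  importance-sampling one, not the knowledge buffer's: with K = 2 drawn
  from a 400-sample pool and a 32-unit model, choosing *which* two
  samples to ask about dominates, whereas buffer memory matters more when
  per-round knowledge is scarce relative to model capacity (deep models,
  large label spaces). Expect the buffer to dominate only with deeper
  server fine-tuning, at the price of self-training's contribution.
- Per-round ε only; across T rounds the naive composition is T·ε.
- The FedAvg+LDP comparator uses our own concretization (L2 clip S, then
  per-coordinate Laplace noise of scale 2·S·d_eff/ε with d_eff the
  parameter count, a conservative L1-sensitivity bound); it documents its
  realized budget rather than claiming equivalence to any published
  baseline's protection.
- ε = 0 makes β = 0 and the debiased estimator undefined; runs reject it
  before round 1. β = 1 (enormous ε) is allowed and reproduces the no-DP
  variant exactly.
- Macro-F1 treats per-class 0/0 as 0.

## Reproducibility

Every source of randomness flows through generators derived from the run
seed via `SeedSequence([seed, stream, round, client])`, so runs are
bit-identical under a fixed config and seed — including the Monte-Carlo
mechanisms tests. Suite replication seeds derive as
`crc32(f"{variant}:{rep}") XOR master` (kept below 2³¹).
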