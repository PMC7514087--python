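# pfdcluster

Density peak clustering with a potential-field-diffusion density measure
(PFD-DPC), plus the classic DPC baseline, external validation indices and
seeded generators for the standard clustering shape benchmarks.

## The problem

Density peak clustering (DPC) picks cluster centers as points that combine
high local density ρ with a large distance δ to any denser point, then
assigns every remaining point to the cluster of its nearest denser
neighbor. Two well-known failure modes motivate this package:

* **Variable density** — in a dataset with one dense and one sparse
  cluster, every point of the sparse cluster has low ρ, so both centers
  land in the dense cluster and the sparse one is never found.
* **Attached allocation errors** — a single point that inherits the wrong
  parent's label drags its whole descendant chain into the wrong cluster
  (ring- and path-shaped clusters suffer most).

## The method

PFD-DPC replaces the kernel density with a similarity built on the
K-nearest-neighbor graph. For a mutual-KNN pair (i, j) with common
neighbors ω(i, j) = σ(i) ∩ σ(j):

```
θ(i, j) = |ω(i, j)|² / Σ_{p∈ω(i,j)} (d_ip² + d_jp²)          potential field
S_k(i)  = Σ over all K^k paths i→x₁→…→x_k of Σ edge d²        k-layer diffusion
Θ(i, j) = θ(i, j) · S_k(i)                                     PFD similarity
ρ_i     = Σ_{j ∈ T(i)} Θ(i, j)      T(i) = top-K Θ neighbors   local density
δ_i     = min_{j: ρ_j > ρ_i} d_ij   (max over others' δ for the peak)
γ_i     = ρ_i · δ_i                                            center score
```

The diffusion factor S_k grows with the distances a point's neighborhood
spans, so sparse regions are boosted and low-density clusters compete for
centers on equal terms. The m largest-γ points become centers; labels then
spread in two steps: (1) a FIFO breadth-first pass along *similar-point*
edges — pairs sharing more than ⌈(K+1)/2⌉ common neighbors — and (2) a
round-based KNN majority vote for everything the similar graph did not
reach. Setting `diffusion=False` reproduces the plain potential-field
ablation (Θ = θ).

The package also implements baseline DPC (cutoff and Gaussian kernels, the
border/halo noise rule), the AMI / ARI / FMI validation indices computed
from the contingency table, and six seeded synthetic stand-ins for the
classic benchmarks (Jain-style moons, 3-arm spiral, ring-with-blobs,
15-Gaussian grid, 7-blob aggregation, 16 Gaussians in 512-D).

## Worked example

```python
from pfdcluster import FixtureSpec, PFDParams, cluster, evaluate, generate

ps = generate(FixtureSpec(shape="jain_moons", seed=0))   # 373 points, two moons
for diffusion in (False, True):
    a, stats = cluster(ps, PFDParams(K=28, k=3, diffusion=diffusion), 2)
    rep = evaluate(ps.y_true, a.labels)
    print(diffusion, ps.y_true[a.centers].tolist(), round(rep.ami, 4))
```

prints

```
False [0, 0] -0.002
True [0, 1] 1.0
```

Without diffusion both γ-selected centers sit in the dense moon (label 0)
and the sparse moon is split arbitrarily (AMI ≈ 0). With three diffusion
layers one center lands in each moon and the ground-truth partition is
recovered exactly (AMI = ARI = FMI = 1). The `examples/` directory holds
this and three more narrated scripts (baseline comparison on the ring
shape, decision-graph export, K-stability sweep).

The same pipeline is available from the shell:

```
pfdcluster synth --shape jain_moons --seed 0 --output moons.txt
pfdcluster cluster --input moons.txt --label-col last -m 2 --K 28 --k 3
pfdcluster dpc     --input moons.txt --label-col last -m 2 --dc 2.0 --halo
pfdcluster sweep   --input moons.txt --label-col last -m 2 --K-range 4:50:2
```

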