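"""Why diffusion matters: clustering two crescents of unequal density.

Builds the Jain-style two-moon benchmark (the outer moon has a third of the
points of the inner one), then clusters it twice: once with the plain
common-neighbor potential field and once with the field diffused three
layers through the KNN graph. The printed center locations show the
ablated variant spending both centers on the dense moon, while the diffused
density places one center per moon and recovers the partition exactly.
"""

from pfdcluster import FixtureSpec, PFDParams, cluster, evaluate, generate

ps = generate(FixtureSpec(shape="jain_moons", seed=0))
print(f"dataset: {ps.source} (n={ps.n}, dense moon = label 0, sparse moon = label 1)")

for label, params in [
    ("no diffusion ", PFDParams(K=28, k=3, diffusion=False)),
    ("3-layer diffusion", PFDParams(K=28, k=3)),
]:
    assignment, stats = cluster(ps, params, 2)
    rep = evaluate(ps.y_true, assignment.labels)
    moons = ps.y_true[assignment.centers].tolist()
    print(
        f"{label}: centers in moons {moons}  "
        f"AMI={rep.ami:.4f} ARI={rep.ari:.4f} FMI={rep.fmi:.4f}"
    )
# centers in moons [0, 0] means both cluster seeds sit in the dense moon —
# the sparse moon is then split instead of recognized as its own cluster.
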