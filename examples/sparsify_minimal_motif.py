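"""Strip a trained adaptation network down to its minimal functional motif.

With the input forbidden from acting on the helper gene, the incoherent
feed-forward architecture is impossible, and iterative link deletion with
retraining converges on the three-link negative feedback loop — the other
elementary adaptation motif.
"""

from netdistill.interrogation import SparsifyConfig, sparsify
from netdistill.tasks import make_adaptation_task
from netdistill.training import TrainConfig

config = SparsifyConfig(seed=0,
                        train_config=TrainConfig(patience_evals=30))
steps = sparsify(
    make_adaptation_task(),
    config,
    initial_mask=[("I1", "g2")],  # input may only act on the output gene
)

names = steps[0].topology.node_names
for k, step in enumerate(steps):
    links = ", ".join(
        f"{names[i]}{'->' if s > 0 else '-|'}g{j + 1}"
        for i, j, s in step.topology.links())
    print(f"step {k}: {step.topology.n_links} links [{links}] "
          f"loss {step.loss:.3f} "
          f"sens {step.metrics.sensitivity:.2f} "
          f"err {step.metrics.adaptation_error:.3f} "
          f"{'ok' if step.success else 'FAILED - too few links to adapt'}")

terminal = [s for s in steps if s.success][-1].topology
print("terminal motif links:", terminal.links())
# expected: I1 -> g1 plus a two-gene cycle of opposite signs (negative
# feedback); deleting any further link destroys adaptation
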