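"""Check that discovered topologies are biochemically implementable.

A network distilled from a trained neural model might rely on response
shapes no real regulation can produce.  The feasibility check recasts the
signed topology as a Hill-function ODE model (activation terms additive,
repression multiplicative, n = 2) and asks whether random parameter sets —
every K and b drawn from Exp(1) — can achieve the function.  A topology
passes when at least 2 parameter sets succeed.
"""

from netdistill.hill import (
    minimal_iff_adaptation,
    minimal_nfb_adaptation,
    p53_like_oscillator,
    robustness_search,
    two_node_controlled_oscillator,
)

print("adaptation (20,000 random parameter sets each):")
for name, topo in [("incoherent feed-forward", minimal_iff_adaptation()),
                   ("negative feedback", minimal_nfb_adaptation())]:
    n = robustness_search(topo, "adaptation", 20000, seed=0)
    print(f"  {name}: {n} successful parameter sets "
          f"-> {'transfers' if n >= 2 else 'does NOT transfer'}")

print("controlled oscillation:")
for name, topo, samples in [
        ("two-node relaxation oscillator", two_node_controlled_oscillator(),
         160000),
        ("p53-like three-node oscillator", p53_like_oscillator(), 20000)]:
    n = robustness_search(topo, "oscillation", samples, seed=0)
    print(f"  {name}: {n} / {samples} successful "
          f"-> {'transfers' if n >= 2 else 'does NOT transfer'}")
# success counts are the topology's robustness: how much of parameter space
# realizes the function
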