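"""Shared study conditions for the analysis scripts.

One synthetic developmental series (egg & nymph -> pupa -> adult analogue)
drives all numbered analyses: 2,000 genes, 500k tags per stage library,
10% of genes planted as 4-fold DE between consecutive stages, 60% complete
digestion, 0.1% per-base error.  The simulation is cached under scratch/ so
the later scripts reuse the exact same draw; results tables go to
results/analysis/.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from tagdge.simulate import SimulationConfig, simulate_experiment

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results" / "analysis"

SEED = 20260925
STAGES = ("egg_nymph", "pupa", "adult")
CONFIG = SimulationConfig(n_genes=2000, library_size=500_000, seed=SEED)


def load_experiment():
    """Simulate (or reload) the shared three-stage experiment."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cache = SCRATCH / f"experiment_seed{SEED}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    exp = simulate_experiment(CONFIG, STAGES)
    with open(cache, "wb") as fh:
        pickle.dump(exp, fh)
    return exp
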