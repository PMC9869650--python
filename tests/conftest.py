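import json
from pathlib import Path

import numpy as np
import pytest

from designbench import fixtures as fx
from designbench.io_formats import (ALPHABET, read_dataset_map,
                                    write_prediction_csv)
from designbench.metrics import ScoredResidue


def random_scored(rng: np.random.Generator, n: int,
                  n_chains: int = 3) -> list[ScoredResidue]:
    """Random scored residues with normalized random probability vectors
    and random stratification labels."""
    letters = rng.choice(list(ALPHABET), size=n)
    probs = rng.random((n, 20))
    probs /= probs.sum(axis=1, keepdims=True)
    fold_classes = ["mainly-alpha", "mainly-beta", "alpha-beta", "special"]
    out = []
    for i in range(n):
        chain = f"ch{rng.integers(n_chains)}_A"
        out.append(ScoredResidue(
            chain_key=chain, aa_true=str(letters[i]), probs=probs[i],
            ss=str(rng.choice(["H", "E", "C"])),
            fold_class=str(rng.choice(fold_classes)),
            architecture_code=f"{rng.integers(1, 5)}.10",
            resolution=float(1.0 + 2.0 * rng.random())))
    return out


@pytest.fixture(scope="session")
def toy_benchmark(tmp_path_factory):
    """A generated toy benchmark on disk plus prediction CSVs for a
    perfect and a noisy synthetic predictor."""
    root = tmp_path_factory.mktemp("toy_benchmark")
    manifest = fx.make_toy_benchmark(root, seed=7)
    truths = json.loads((root / "truth_sequences.json").read_text())
    parts = [fx.make_predictions(seq, fx.PredictorSpec(kind="perfect"),
                                 chain_key=ck)
             for ck, seq in sorted(truths.items())]
    write_prediction_csv(fx.concat_predictions("perfect", parts),
                         root / "perfect.csv")
    parts = [fx.make_predictions(
        seq, fx.PredictorSpec(kind="softmax_noise", temperature=0.8, seed=3),
        chain_key=ck) for ck, seq in sorted(truths.items())]
    write_prediction_csv(fx.concat_predictions("noisy", parts),
                         root / "noisy.csv")
    return {"root": Path(root), "manifest": manifest, "truths": truths,
            "dmap": read_dataset_map(root / "dataset_map.txt")}
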