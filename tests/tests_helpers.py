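"""Shared toy-dataset builder used by estimation and acceptance tests."""

import numpy as np
import pandas as pd

from ppgbp.dataset import CalibratedDataset


def toy_dataset(n_participants=5, rows_per=30, n_features=4, noise=0.5,
                seed=0, nonlinear=False):
    """Cohort dataset with a known feature -> dBP link."""
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        X = rng.normal(size=(rows_per, n_features))
        if nonlinear:
            y = 8.0 * (X[:, 0] > 0) + noise * rng.normal(size=rows_per)
        else:
            y = 3.0 * X[:, 0] + noise * rng.normal(size=rows_per)
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_features)])
        df["dsbp"] = y
        df["participant_id"] = f"P{p}"
        df["t"] = np.arange(rows_per, dtype=float)
        df["augmented"] = (np.arange(rows_per) % 3) == 1
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    feature_cols = [f"f{j}" for j in range(n_features)]
    return CalibratedDataset(
        X=table[["t"] + feature_cols], y=table[["dsbp"]],
        participant_ids=table["participant_id"].to_numpy(),
        augmented_mask=table["augmented"].to_numpy(),
        dynamic_features=feature_cols, demographic_features=[])
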