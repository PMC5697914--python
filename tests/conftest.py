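import numpy as np
import pandas as pd
import pytest

from dendroscale.spines import SPINE_COLUMNS, SpineDataset


def make_spine_df(branches: dict[str, list[tuple[float, dict[float, float], str]]],
                  cell_id: str = "c0") -> pd.DataFrame:
    """Build a tidy spine table from {branch: [(position, {tp: size}, fate)]}."""
    rows = []
    for branch, spines in branches.items():
        for i, (pos, sizes, fate) in enumerate(spines):
            for tp, size in sizes.items():
                rows.append((cell_id, branch, f"s{i:03d}", pos, tp, size, fate))
    return pd.DataFrame(rows, columns=SPINE_COLUMNS)


@pytest.fixture
def clustered_branch_dataset():
    """Branches whose size increases occur in contiguous spatial blocks.

    Used to check that the cluster analysis detects genuine spatial
    clustering against its position-shuffle null.
    """

    def build(seed: int, n_branches: int = 40, n_spines: int = 14) -> SpineDataset:
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(n_branches):
            pos = np.cumsum(0.5 + rng.exponential(3.5, n_spines))
            inc = np.zeros(n_spines, bool)
            for c in rng.choice(n_spines, 2, replace=False):
                inc[max(0, c - 1):c + 2] = True
            sizes = np.where(inc, 1.3, 1.0) * np.exp(rng.normal(0, 0.03, n_spines))
            for i in range(n_spines):
                rows.append(("c0", f"b{b:02d}", f"s{i:03d}", pos[i], 48.0,
                             sizes[i], "stable"))
        df = pd.DataFrame(rows, columns=SPINE_COLUMNS)
        df["size_norm"] = df["size"]
        return SpineDataset(df)

    return build
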