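import numpy as np
import pandas as pd
import pytest

from epiclone import SimParams


@pytest.fixture
def small_params():
    return SimParams(
        n_loci=20, n_background_loci=10, n_cells=50, n_clones=4,
        p_demeth=0.3, probes_per_block=3, seed=7,
    )


@pytest.fixture
def tiny_manifest():
    """Hand-built probe manifest: 2 genes plus an intergenic run."""
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(1, 9)],
            "chrom": ["chr1"] * 8,
            "pos": [100, 200, 300, 5000, 5100, 9000, 9500, 20000],
            "gene": ["GENEA", "GENEA", "GENEA", "GENEB", "GENEB", "", "", ""],
            "region_class": ["TSS200", "TSS200", "body", "TSS200", "TSS200",
                             "intergenic", "intergenic", "intergenic"],
            "cgi_class": ["island", "island", "open_sea", "island", "island",
                          "open_sea", "open_sea", "open_sea"],
        }
    )


def brute_force_complete_linkage(points: np.ndarray) -> list[float]:
    """O(n^3) agglomerative complete-linkage oracle: sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    np.linalg.norm(points[a] - points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return heights
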