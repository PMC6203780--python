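"""Genotype-based kinship estimation and relatedness filtering.

Kinship is estimated with the robust between-family moment estimator
built on heterozygote concordance (the KING-robust form): for a pair
(i, j) over shared hard-call genotypes,

    phi_hat = ( N_Aa,Aa - 2 * N_AA,aa ) / ( 2 * min(N_Aa^i, N_Aa^j) )
              + 1/2 - ( N_Aa^i + N_Aa^j ) / ( 4 * min(N_Aa^i, N_Aa^j) )

where N_Aa,Aa counts SNPs at which both are heterozygous, N_AA,aa counts
opposite homozygotes, and N_Aa^i is the heterozygote count of individual
i.  Expectations: ~0.5 for duplicates, 0.25 for full siblings, 0.125 for
second-degree relatives, 0 for unrelated pairs — without requiring allele
frequencies, so the estimate is robust to population structure.

Dozens of GRS SNPs are far too few for stable kinship estimates; use a
dedicated panel of a few thousand SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["estimate_kinship", "filter_related"]


def estimate_kinship(
    dosages: pd.DataFrame, min_snps: int = 100
) -> pd.DataFrame:
    """Pairwise kinship for every unordered pair of participants.

    Requires hard-call dosages in {0, 1, 2} (NaN treated as missing).
    Pairs sharing fewer than ``min_snps`` non-missing SNPs get
    ``kinship = NaN`` and ``flagged = True`` instead of an estimate.
    Returns a DataFrame with columns id_a, id_b, kinship, n_snps, flagged.
    """
    G = dosages.to_numpy(dtype=float)
    obs = ~np.isnan(G)
    vals = np.where(obs, G, -1.0)
    if not np.isin(vals[obs.nonzero()], [0.0, 1.0, 2.0]).all():
        raise ValueError("kinship estimation requires hard-call dosages in {0,1,2}")
    het = (vals == 1.0) & obs
    aa = (vals == 0.0) & obs
    AA = (vals == 2.0) & obs

    hetf = het.astype(np.float32)
    aaf = aa.astype(np.float32)
    AAf = AA.astype(np.float32)
    obsf = obs.astype(np.float32)

    n_hethet = hetf @ hetf.T
    n_opp = AAf @ aaf.T + aaf @ AAf.T
    n_shared = obsf @ obsf.T
    # per-individual het counts restricted to SNPs observed in the partner
    het_i = hetf @ obsf.T  # het count of row i over SNPs observed in j
    het_j = het_i.T
    het_min = np.minimum(het_i, het_j)

    n = G.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (
            (n_hethet - 2.0 * n_opp) / (2.0 * het_min)
            + 0.5
            - (het_i + het_j) / (4.0 * het_min)
        )
    kin = phi[iu, ju].astype(float)
    shared = n_shared[iu, ju].astype(int)
    flagged = (shared < min_snps) | ~np.isfinite(kin)
    kin = np.where(flagged, np.nan, kin)
    ids = np.asarray(dosages.index)
    return pd.DataFrame(
        {
            "id_a": ids[iu],
            "id_b": ids[ju],
            "kinship": np.clip(kin, -0.5, 0.5),
            "n_snps": shared,
            "flagged": flagged,
        }
    )


def filter_related(
    pairs: pd.DataFrame, threshold: float = 0.08, seed: int = 0
) -> set:
    """Greedy randomised removal of one member per related pair.

    Pairs with kinship above ``threshold`` are visited in random order;
    for each pair whose members both survive so far, one member (chosen at
    random) is dropped.  The returned kept-id set contains no pair above
    the threshold.  Reproducible given the seed.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")
    required = {"id_a", "id_b", "kinship"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    all_ids = set(pairs["id_a"]) | set(pairs["id_b"])
    hits = pairs.loc[pairs["kinship"] > threshold, ["id_a", "id_b"]]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(hits))
    dropped: set = set()
    rows = hits.to_numpy()
    for k in order:
        a, b = rows[k]
        if a in dropped or b in dropped:
            continue
        dropped.add(a if rng.random() < 0.5 else b)
    return all_ids - dropped
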