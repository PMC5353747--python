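"""Concordant biosets, Venn partitioning, percentages and concordance."""

import numpy as np
import pytest

from sigoverlap import (
    UniverseSpec,
    contribution_percentage,
    derive_concordant_bioset,
    direction_concordance,
    directional_decomposition,
    venn_partition,
)
from sigoverlap.celltypes import BiosetMember, ConcordantBioset

from conftest import make_signature


def _bioset(directed, name="bio"):
    members = tuple(
        BiosetMember(g, d) for g, d in sorted(dict(directed).items())
    )
    return ConcordantBioset(name=name, members=members, sources=("q", "r"))


def _decomposition(q_dirs, r_dirs, extra_universe=200):
    genes = sorted(set(q_dirs) | set(r_dirs)) + [f"BG{i}" for i in range(extra_universe)]
    uni = UniverseSpec(genes)
    q = make_signature(sorted(q_dirs.items()), name="q")
    r = make_signature(sorted(r_dirs.items()), name="r")
    return directional_decomposition(q, r, uni), q, r


def test_bioset_is_union_of_same_direction_cells():
    dd, q, r = _decomposition({"A": "up", "B": "down"}, {"A": "up", "B": "down"})
    bio = derive_concordant_bioset(dd, ("q", "r"), query_signature=q, reference_signature=r)
    assert bio.directions() == {"A": "up", "B": "down"}
    member = bio.members[0]
    assert member.query_p == q.entries[0].p_value
    assert member.reference_fold_change == r.entries[0].signed_fold_change


def test_only_discordant_genes_gives_empty_bioset():
    dd, *_ = _decomposition({"A": "up", "B": "down"}, {"A": "down", "B": "up"})
    bio = derive_concordant_bioset(dd, ("q", "r"))
    assert len(bio) == 0


def test_bioset_size_equals_concordant_cell_counts():
    q_dirs = {f"G{i}": ("up" if i % 2 else "down") for i in range(20)}
    r_dirs = {f"G{i}": ("up" if i % 3 else "down") for i in range(15)}
    dd, *_ = _decomposition(q_dirs, r_dirs)
    bio = derive_concordant_bioset(dd, ("q", "r"))
    assert len(bio) == dd.count(("up", "up")) + dd.count(("down", "down"))


def test_venn_partition_example():
    bio = _bioset({"A": "up", "B": "up", "C": "down"})
    part = venn_partition(bio, {"A", "B"}, {"B"}, set(), labels=("FS", "AS", "OL"))
    assert part.region_counts[(True, False, False)] == 1  # FS only: A
    assert part.region_counts[(True, True, False)] == 1  # FS & AS: B
    assert part.region_counts[(False, False, False)] == 1  # none: C
    assert part.marginal("FS") == 2 and part.marginal("AS") == 1 and part.marginal("OL") == 0
    assert part.exclusive("FS") == 1


def test_venn_partition_all_sets_empty():
    bio = _bioset({"A": "up", "B": "down", "C": "up"})
    part = venn_partition(bio, set(), set(), set())
    assert part.region_counts[(False, False, False)] == 3
    assert sum(part.region_counts.values()) == 3


def test_venn_partition_matches_membership_pattern_oracle(rng):
    genes = [f"G{i:03d}" for i in range(400)]
    bio_genes = rng.choice(genes, size=200, replace=False)
    bio = _bioset({str(g): str(d) for g, d in
                   zip(bio_genes, rng.choice(["up", "down"], size=200))})
    sets = [set(map(str, rng.choice(genes, size=s, replace=False))) for s in (90, 60, 120)]
    part = venn_partition(bio, *sets)
    # oracle: tally each gene's 3-bit membership pattern directly
    tally: dict[tuple, int] = {}
    for g in bio.gene_set:
        key = tuple(g in s for s in sets)
        tally[key] = tally.get(key, 0) + 1
    for key, count in part.region_counts.items():
        assert count == tally.get(key, 0)
    assert sum(part.region_counts.values()) == len(bio)
    for i, lab in enumerate(part.labels):
        covering = sum(c for k, c in part.region_counts.items() if k[i])
        assert part.marginal(lab) == covering


@pytest.mark.parametrize(
    "count, size, expected",
    [(44, 141, 31.2), (56, 231, 24.2), (0, 141, 0.0), (1, 8, 12.5), (1, 16, 6.3)],
)
def test_contribution_percentage_round_half_up(count, size, expected):
    assert contribution_percentage(count, size) == expected


def test_contribution_percentage_errors():
    with pytest.raises(ValueError):
        contribution_percentage(1, 0)
    with pytest.raises(ValueError):
        contribution_percentage(5, 4)


def test_direction_concordance_examples():
    bio = _bioset({"A": "up"})
    assert direction_concordance(bio, make_signature([("A", "up")])) == (1, 1)
    assert direction_concordance(bio, make_signature([("A", "down")])) == (1, 0)
    assert direction_concordance(bio, make_signature([("B", "up")])) == (0, 0)


def test_direction_concordance_matches_brute_force(rng):
    genes = [f"G{i:03d}" for i in range(150)]
    bio_dirs = {str(g): str(d) for g, d in
                zip(rng.choice(genes, 60, replace=False), rng.choice(["up", "down"], 60))}
    sig_dirs = {str(g): str(d) for g, d in
                zip(rng.choice(genes, 80, replace=False), rng.choice(["up", "down"], 80))}
    bio = _bioset(bio_dirs)
    sig = make_signature(sorted(sig_dirs.items()))
    n_shared, n_same = direction_concordance(bio, sig)
    shared = set(bio_dirs) & set(sig_dirs)
    assert n_shared == len(shared)
    assert n_same == sum(1 for g in shared if bio_dirs[g] == sig_dirs[g])
    assert n_same <= n_shared
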