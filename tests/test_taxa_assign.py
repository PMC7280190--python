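"""Per-read classification, chimera flagging, and de novo grouping."""

import numpy as np
import pytest

from amf_otufree import simulate as sim
from amf_otufree.alignment import AlignmentHit
from amf_otufree.preprocess import AmpliconRead
from amf_otufree.refdb import ReferenceRecord
from amf_otufree.taxa_assign import (
    DeNovoGroup,
    TaxonLabel,
    assign_reads,
    classify_known,
    cluster_de_novo,
    export_representatives,
    flag_chimera,
    import_external_names,
    sequence_relation,
)

from _oracles import connected_components


def _mutate(seq, n_subs, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def test_classification_thresholds_are_inclusive():
    hit = AlignmentHit("q", "s", coverage=80.0, identity=97.0, score=100.0)
    assert hit.meets(80, 97)
    assert not AlignmentHit("q", "s", 79.9, 99.5, 100.0).meets(80, 97)
    assert not AlignmentHit("q", "s", 100.0, 96.9, 100.0).meets(80, 97)


def test_classify_known_true_taxon_and_unclassified(small_truth, small_refdb, rng):
    name = small_truth.in_db[0]
    read = _mutate(small_truth.taxa[name], 4, rng)  # 1% error on 400 nt
    asn = classify_known(read, small_refdb)
    assert asn.label == TaxonLabel("known", name)
    assert asn.best_hit.identity >= 97.0
    noise = random_dna(rng, 400)
    assert classify_known(noise, small_refdb).label is None
    # withheld taxa diverge too far from every database entry
    withheld = next(iter(small_truth.withheld))
    assert classify_known(small_truth.taxa[withheld], small_refdb).label is None


def test_classify_known_rejects_empty_database():
    with pytest.raises(ValueError):
        classify_known("ACGTACGT", [])


def test_best_hit_tie_breaks_lexicographically(rng):
    core = random_dna(rng, 200)
    refs = [
        ReferenceRecord("ZZZ", "Taxon Z", core + "AAAAAAAA"),
        ReferenceRecord("AAA", "Taxon A", core + "TTTTTTTT"),
    ]
    asn = classify_known(core, refs)
    assert asn.best_hit.subject_accession == "AAA"
    assert asn.label.name == "Taxon A"


def test_chimera_flagged_and_pure_reads_not(small_truth, small_refdb, rng):
    a, b = small_truth.in_db[0], small_truth.in_db[1]
    sa, sb = small_truth.taxa[a], small_truth.taxa[b]
    chimera = sa[:200] + sb[200:]
    assert classify_known(chimera, small_refdb).label is None
    assert flag_chimera(chimera, small_refdb)
    assert not flag_chimera(sa, small_refdb)
    assert not flag_chimera(random_dna(rng, 400), small_refdb)


def test_relation_is_symmetric(rng):
    for trial in range(10):
        base = random_dna(rng, 150)
        other = _mutate(base, int(rng.integers(0, 10)), rng)[: int(rng.integers(120, 151))]
        assert sequence_relation(base, other) == sequence_relation(other, base)


def test_single_linkage_chain_groups_together(rng):
    b = random_dna(rng, 200)
    a = _mutate(b, 4, rng)  # 98% to b
    rng2 = np.random.default_rng(99)
    c = _mutate(b, 4, rng2)
    # a-c differ at ~8 positions: below 97%; the chain still joins them
    assert sequence_relation(a, b) and sequence_relation(b, c)
    if sequence_relation(a, c):
        pytest.skip("mutations overlapped; chain premise not met")
    groups = cluster_de_novo([("a", a), ("b", b), ("c", c)])
    assert len(groups) == 1 and len(groups[0].member_ids) == 3


def test_unrelated_reads_become_singletons(rng):
    reads = [(f"r{i}", random_dna(rng, 150)) for i in range(6)]
    groups = cluster_de_novo(reads)
    assert len(groups) == 6
    assert [g.label.name for g in groups] == [f"de novo_{k}" for k in range(1, 7)]


@pytest.mark.parametrize("trial", range(8))
def test_grouping_equals_brute_force_connected_components(trial):
    """Random instances: clustering == components of the pairwise relation."""
    rng = np.random.default_rng(2000 + trial)
    n_fam = int(rng.integers(2, 5))
    seqs = []
    for fam in range(n_fam):
        base = random_dna(rng, 160)
        for _ in range(int(rng.integers(1, 6))):
            seqs.append(_mutate(base, int(rng.integers(0, 4)), rng))
    for _ in range(int(rng.integers(0, 4))):
        seqs.append(random_dna(rng, 160))
    reads = [(f"r{i}", s) for i, s in enumerate(seqs)]
    groups = cluster_de_novo(reads, method="exact")
    got = {frozenset(int(m[1:]) for m in g.member_ids) for g in groups}
    want = set(
        connected_components(len(seqs), lambda i, j: sequence_relation(seqs[i], seqs[j]))
    )
    assert got == want


def test_indexed_clustering_matches_exact_on_well_separated_taxa(small_truth, rng):
    seqs = []
    for name in small_truth.in_db[:4]:
        for _ in range(12):
            seqs.append(_mutate(small_truth.taxa[name], 3, rng))
    reads = [(f"r{i}", s) for i, s in enumerate(seqs)]
    exact = {frozenset(g.member_ids) for g in cluster_de_novo(reads, method="exact")}
    indexed = {frozenset(g.member_ids) for g in cluster_de_novo(reads, method="indexed")}
    assert exact == indexed


def test_group_labels_ordered_by_size_then_first_read(rng):
    big = random_dna(rng, 150)
    small = random_dna(rng, 150)
    reads = [("s1", small)] + [(f"b{i}", _mutate(big, 1, rng)) for i in range(3)]
    groups = cluster_de_novo(reads)
    assert groups[0].label.name == "de novo_1" and len(groups[0].member_ids) == 3
    assert groups[1].member_ids == ["s1"]


def test_export_and_import_external_names(tmp_path, rng):
    g1 = DeNovoGroup(TaxonLabel("de_novo", "de novo_1"), ["a", "b"], ["ACGT" * 30, "ACGT" * 25])
    g2 = DeNovoGroup(TaxonLabel("de_novo", "de novo_2"), ["c"], ["TTTT" * 28])
    path = tmp_path / "reps.fasta"
    export_representatives([g1, g2], path)
    text = path.read_text()
    assert ">de novo_1\n" + "ACGT" * 30 in text and ">de novo_2" in text
    names = import_external_names([g1, g2], {"de novo_1": "Uncultured Archeospora"})
    assert names == {"de novo_1": "Uncultured Archeospora", "de novo_2": "de novo_2"}
    assert import_external_names([g1, g2], {}) == {
        "de novo_1": "de novo_1", "de novo_2": "de novo_2"
    }
    with pytest.raises(KeyError):
        import_external_names([g1, g2], {"de novo_9": "x"})


def test_assignment_partition_sums_to_input(small_truth, small_refdb):
    meta = sim.vineyard_design(n_replicates=1)
    comps = sim.study_compositions(small_truth, meta, seed=21)
    mids = sim.make_mid_map(list(meta.index), seed=21)
    reads, tt = sim.simulate_reads(
        small_truth, comps, 80, mids, error_rate=0.005, chimera_fraction=0.05,
        junk_fraction=0.0, seed=22,
    )
    tag = len(next(iter(mids.values())))
    per_sample = {}
    for r in reads:
        sample = tt.set_index("read_id").loc[r.read_id, "sample"]
        r.sequence = r.sequence[tag:]
        r.qualities = r.qualities[tag:]
        r.sample_id = sample
        per_sample.setdefault(sample, []).append(r)
    assignments, groups = assign_reads(per_sample, small_refdb)
    n = len(assignments)
    n_known = sum(1 for a in assignments if a.label and a.label.kind == "known")
    n_dn = sum(1 for a in assignments if a.label and a.label.kind == "de_novo")
    n_chim = sum(1 for a in assignments if a.chimera_flag)
    n_noise = sum(1 for a in assignments if a.label is None and not a.chimera_flag)
    assert n_known + n_dn + n_chim + n_noise == n == len(reads)
    for a in assignments:
        if a.chimera_flag:
            assert a.label is None  # chimeras are never labelled
        if a.label and a.label.kind == "known":
            assert a.best_hit.meets(80, 97)
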