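import numpy as np
import pytest

from phylokmer import (
    ClassifierConfig,
    HitDistribution,
    IndexConfig,
    SimulationConfig,
    Status,
    apply_alpha_filter,
    build_index,
    classify_pair,
    classify_read,
    classify_sample,
    decompose_lineages,
    map_read,
    simulate_reads,
)
from phylokmer.classify import PairingError
from phylokmer.simulate import generate_tree, evolve_genomes

from oracles import brute_kmer_to_leaves, brute_lca_set, revcomp


def hits_of(counts, mapped=None, total=None):
    mapped = mapped if mapped is not None else sum(counts.values())
    return HitDistribution(counts=counts, mapped_kmers=mapped, total_kmers=total or mapped)


class TestMapRead:
    def test_hits_lie_on_source_root_path(self, toy_index, toy_tree):
        """Hits from an error-free read match brute-force k-mer placement."""
        index, genomes = toy_index
        read = genomes["A"][0][:40]
        hits = map_read(read, index)
        table = brute_kmer_to_leaves(genomes, 7)
        from oracles import string_canonical_kmers

        expected = {}
        for kmer in string_canonical_kmers(read, 7):
            leaves = table[kmer]
            node = brute_lca_set(toy_tree, [toy_tree.leaf_name_index[l] for l in leaves])
            expected[node] = expected.get(node, 0) + 1
        assert hits.counts == expected
        path = set(toy_tree.root_path(toy_tree.node_by_label("A")))
        assert set(hits.counts) <= path

    def test_bookkeeping_totals(self, toy_index):
        index, genomes = toy_index
        read = genomes["B"][0][:30]
        hits = map_read(read, index)
        assert hits.total_kmers == len(read) - index.config.k + 1
        assert sum(hits.counts.values()) == hits.mapped_kmers <= hits.total_kmers
        assert sum(c for _, c in hits.runs) == hits.total_kmers

    def test_short_read_empty_distribution(self, toy_index):
        index, _ = toy_index
        hits = map_read("ACG", index)
        assert hits.total_kmers == 0 and not hits.counts

    def test_foreign_read_misses(self, random_community):
        tree, genomes = random_community(2, n_leaves=4)
        index = build_index({l: [s] for l, s in genomes.items()}, tree, IndexConfig(k=31))
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=150))
        hits = map_read(read, index)
        assert hits.mapped_kmers == 0


class TestDecomposeLineages:
    def test_single_chain_sums_support(self, toy_tree):
        a, ab = toy_tree.node_by_label("A"), toy_tree.node_by_label("AB")
        groups = decompose_lineages(hits_of({a: 5, ab: 2}), toy_tree)
        assert len(groups) == 1
        assert groups[0].terminal == a and groups[0].support == 7

    def test_disjoint_terminals(self, toy_tree):
        a, b = toy_tree.node_by_label("A"), toy_tree.node_by_label("B")
        groups = decompose_lineages(hits_of({a: 5, b: 5}), toy_tree)
        assert {(g.terminal, g.support) for g in groups} == {(a, 5), (b, 5)}

    def test_internal_only_hit_is_its_own_terminal(self, toy_tree):
        ab = toy_tree.node_by_label("AB")
        groups = decompose_lineages(hits_of({ab: 4}), toy_tree)
        assert [(g.terminal, g.support) for g in groups] == [(ab, 4)]

    def test_shared_ancestor_supports_both_lineages(self, toy_tree):
        a, b, ab = (toy_tree.node_by_label(x) for x in ("A", "B", "AB"))
        groups = decompose_lineages(hits_of({a: 3, b: 2, ab: 4}), toy_tree)
        by_terminal = {g.terminal: g.support for g in groups}
        assert by_terminal == {a: 7, b: 6}

    def test_empty_hits(self, toy_tree):
        assert decompose_lineages(HitDistribution(), toy_tree) == []

    def test_brute_force_poset_oracle(self, random_community):
        """Terminals and supports match a direct poset computation."""
        rng = np.random.default_rng(8)
        tree, _ = random_community(8, n_leaves=10)
        for _ in range(50):
            nodes = rng.choice(tree.node_count, size=rng.integers(1, 6), replace=False)
            counts = {int(n): int(rng.integers(1, 10)) for n in nodes}
            groups = decompose_lineages(hits_of(dict(counts)), tree)
            expected_terminals = {
                u
                for u in counts
                if not any(v != u and u in set(tree.root_path(v)) for v in counts)
            }
            assert {g.terminal for g in groups} == expected_terminals
            for g in groups:
                path = set(tree.root_path(g.terminal))
                assert g.support == sum(c for n, c in counts.items() if n in path)


class TestAlphaFilter:
    def test_low_support_lineage_dropped(self, toy_tree):
        a, c = toy_tree.node_by_label("A"), toy_tree.node_by_label("C")
        hits = hits_of({a: 99, c: 1})
        lineages = decompose_lineages(hits, toy_tree)
        kept = apply_alpha_filter(lineages, hits, ClassifierConfig(alpha=0.05))
        assert [g.terminal for g in kept] == [a]

    def test_alpha_zero_keeps_everything(self, toy_tree):
        a, c = toy_tree.node_by_label("A"), toy_tree.node_by_label("C")
        hits = hits_of({a: 99, c: 1})
        lineages = decompose_lineages(hits, toy_tree)
        assert apply_alpha_filter(lineages, hits, ClassifierConfig(alpha=0.0)) == lineages

    def test_fallback_keeps_best_lineage(self, toy_tree):
        a, c = toy_tree.node_by_label("A"), toy_tree.node_by_label("C")
        hits = hits_of({a: 2, c: 1}, mapped=100)  # both below threshold
        lineages = decompose_lineages(hits, toy_tree)
        kept = apply_alpha_filter(lineages, hits, ClassifierConfig(alpha=0.5))
        assert [g.terminal for g in kept] == [a]

    def test_fallback_tie_breaks_to_smaller_preorder_id(self, toy_tree):
        a, c = sorted([toy_tree.node_by_label("A"), toy_tree.node_by_label("C")])
        hits = hits_of({a: 1, c: 1}, mapped=100)
        lineages = decompose_lineages(hits, toy_tree)
        kept = apply_alpha_filter(lineages, hits, ClassifierConfig(alpha=0.5))
        assert [g.terminal for g in kept] == [a]

    def test_monotone_in_alpha(self, random_community):
        """Raising alpha never increases the surviving-lineage count."""
        rng = np.random.default_rng(17)
        tree, _ = random_community(17, n_leaves=10)
        for _ in range(30):
            nodes = rng.choice(tree.node_count, size=4, replace=False)
            hits = hits_of({int(n): int(rng.integers(1, 20)) for n in nodes})
            lineages = decompose_lineages(hits, tree)
            previous = None
            for alpha in [0.0, 0.05, 0.1, 0.2, 0.4, 0.8]:
                kept = apply_alpha_filter(lineages, hits, ClassifierConfig(alpha=alpha))
                if previous is not None:
                    assert len(kept) <= len(previous)
                    assert {g.terminal for g in kept} <= {g.terminal for g in previous}
                previous = kept


class TestClassifyRead:
    def test_unique_read_is_single_lineage_at_leaf(self, toy_index, toy_tree):
        index, genomes = toy_index
        read = genomes["A"][0][:20]  # unique-to-A region
        rc = classify_read("r", read, index, toy_tree)
        assert rc.status is Status.SL
        assert rc.assigned_node == toy_tree.node_by_label("A")
        assert rc.lineages_surviving == 1

    def test_shared_region_read_assigned_to_internal_node(self, toy_index, toy_tree):
        index, genomes = toy_index
        read = genomes["A"][0][24:48]  # region shared verbatim by A and B only
        rc = classify_read("r", read, index, toy_tree)
        assert rc.status is Status.SL
        assert rc.assigned_node == toy_tree.node_by_label("AB")

    def test_chimeric_read_splits_to_root(self, toy_index, toy_tree):
        index, genomes = toy_index
        chimera = genomes["A"][0][:20] + genomes["C"][0][:20]
        rc = classify_read("r", chimera, index, toy_tree, ClassifierConfig(alpha=0.1))
        assert rc.status is Status.SPLIT
        assert rc.assigned_node == toy_tree.root
        assert rc.lineages_surviving >= 2

    def test_no_hits_is_unclassified(self, toy_index, toy_tree):
        index, _ = toy_index
        rc = classify_read("r", "A" * 30, index, toy_tree)
        assert rc.status is Status.UNCLASSIFIED
        assert rc.assigned_node is None and rc.lineages_surviving == 0

    def test_reverse_complement_read_classified_identically(self, toy_index, toy_tree):
        index, genomes = toy_index
        read = genomes["B"][0][:25]
        fwd = classify_read("r", read, index, toy_tree)
        rev = classify_read("r", revcomp(read), index, toy_tree)
        assert (fwd.status, fwd.assigned_node) == (rev.status, rev.assigned_node)

    def test_contaminant_below_alpha_does_not_change_assignment(self, toy_index, toy_tree):
        index, genomes = toy_index
        clean = genomes["A"][0][:40]
        contaminated = clean + genomes["C"][0][:9]  # 3 foreign 7-mers vs ~34 clean
        base = classify_read("r", clean, index, toy_tree, ClassifierConfig(alpha=0.2))
        noisy = classify_read("r", contaminated, index, toy_tree, ClassifierConfig(alpha=0.2))
        assert noisy.assigned_node == base.assigned_node
        assert noisy.status == base.status


class TestClassifySample:
    def test_empty_input(self, toy_index, toy_tree):
        index, _ = toy_index
        assert list(classify_sample([], index, toy_tree)) == []

    def test_placement_soundness_on_simulated_sample(self):
        """Error-free reads land on their source leaf's root path."""
        config = SimulationConfig(n_leaves=10, n_reads=300, seed=23)
        tree, _ = generate_tree(config)
        genomes = evolve_genomes(tree, config)
        index = build_index({l: [s] for l, s in genomes.items()}, tree, IndexConfig(k=31))
        reads, truth = simulate_reads(genomes, config)
        truth_map = dict(truth)
        results = list(classify_sample(reads, index, tree))
        assert len(results) == len(reads)
        classified = [r for r in results if r.status is not Status.UNCLASSIFIED]
        assert classified  # sample must actually exercise the index
        for rc in classified:
            source = tree.leaf_name_index[truth_map[rc.read_id]]
            assert rc.assigned_node in tree.root_path(source)

    def test_status_conservation(self, toy_index, toy_tree):
        index, genomes = toy_index
        reads = [
            ("r1", genomes["A"][0][:20]),
            ("r2", "A" * 30),
            ("r3", genomes["A"][0][:20] + genomes["C"][0][:20]),
        ]
        results = list(classify_sample(reads, index, toy_tree))
        by_status = {s: sum(1 for r in results if r.status is s) for s in Status}
        assert sum(by_status.values()) == len(reads)
        assert by_status[Status.UNCLASSIFIED] == 1

    def test_paired_concatenate_merges_mates(self, toy_index, toy_tree):
        index, genomes = toy_index
        mates1 = [("p1", genomes["A"][0][:20])]
        mates2 = [("p1", genomes["C"][0][:20])]
        results = list(
            classify_sample(mates1, index, toy_tree, ClassifierConfig(alpha=0.1), reads2=mates2)
        )
        assert len(results) == 1
        assert results[0].status is Status.SPLIT  # mates disagree -> split signal
        assert results[0].read_lengths == (20, 20)

    def test_paired_separate_mode(self, toy_index, toy_tree):
        index, genomes = toy_index
        config = ClassifierConfig(paired_mode="separate")
        results = list(
            classify_sample(
                [("p1", genomes["A"][0][:20])],
                index,
                toy_tree,
                config,
                reads2=[("p1/2", genomes["C"][0][:20])],
            )
        )
        assert len(results) == 2

    def test_mate_count_mismatch_raises(self, toy_index, toy_tree):
        index, genomes = toy_index
        with pytest.raises(PairingError):
            list(
                classify_sample(
                    [("a", "ACGT" * 10), ("b", "ACGT" * 10)],
                    index,
                    toy_tree,
                    reads2=[("a", "ACGT" * 10)],
                )
            )

    def test_reads_from_fastq_file(self, toy_index, toy_tree, tmp_path):
        from phylokmer.simulate import write_fastq

        index, genomes = toy_index
        path = tmp_path / "reads.fastq"
        write_fastq([("r1", genomes["A"][0][:20])], path)
        results = list(classify_sample(path, index, toy_tree))
        assert len(results) == 1 and results[0].status is Status.SL


class TestLeaveOneOutSplitSignal:
    def test_removed_leaf_reads_split_within_parent_clade(self):
        """Reads from an unindexed leaf split more than reads from an indexed one,
        and their assignments stay on the parent's root path."""
        enriched = 0
        trials = 0
        for seed in range(6):
            config = SimulationConfig(
                n_leaves=10, n_reads=150, seed=seed, branch_substitution_prob=0.04
            )
            tree, _ = generate_tree(config)
            genomes = evolve_genomes(tree, config)
            # drop a leaf whose sister is a leaf so the clade keeps a reference
            target = None
            for label, leaf_id in sorted(tree.leaf_name_index.items()):
                parent = tree.nodes[leaf_id].parent
                siblings = [c for c in tree.nodes[parent].children if c != leaf_id]
                if all(tree.nodes[s].is_leaf for s in siblings):
                    target = label
                    break
            if target is None:
                continue
            trials += 1
            kept = {l: [s] for l, s in genomes.items() if l != target}
            with pytest.warns(UserWarning):
                index = build_index(kept, tree, IndexConfig(k=31))
            target_id = tree.leaf_name_index[target]
            parent = tree.nodes[target_id].parent
            control = next(l for l in sorted(kept) if l != target)

            def split_fraction(source_label):
                rconf = SimulationConfig(
                    n_leaves=10, n_reads=150, seed=seed + 1000, read_length=150
                )
                reads, _ = simulate_reads({source_label: genomes[source_label]}, rconf)
                results = [
                    classify_read(rid, seq, index, tree, ClassifierConfig(alpha=0.05))
                    for rid, seq in reads
                ]
                classified = [r for r in results if r.assigned_node is not None]
                splits = [r for r in classified if r.status is Status.SPLIT]
                return results, (len(splits) / len(classified) if classified else 0.0)

            novel_results, novel_frac = split_fraction(target)
            _, control_frac = split_fraction(control)
            if novel_frac > control_frac:
                enriched += 1
            # Most assignments concentrate in or above the parent clade;
            # occasional homoplastic k-mers may pull single reads elsewhere.
            parent_path = set(tree.root_path(parent))
            classified = [r for r in novel_results if r.assigned_node is not None]
            in_clade = sum(
                1
                for rc in classified
                if tree.is_ancestor(parent, rc.assigned_node)
                or rc.assigned_node in parent_path
            )
            assert in_clade >= 0.5 * len(classified)
        assert trials >= 3
        assert enriched == trials
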