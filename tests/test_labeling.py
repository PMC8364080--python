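"""Truth labeling: confident filtering, haplotype pairs, prefix-tree matching."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from allelecall.datatypes import CandidateAllele, Hotspot, SiteData
from allelecall.labeling import (
    Cluster,
    TruthSet,
    TruthVariant,
    cluster_sites,
    filter_confident,
    match_candidates,
    truth_haplotype_pairs,
)
from allelecall.pileup import ReferenceView

REF = "".join(
    np.random.default_rng(99).choice(list("ACGT"), size=400)
)
REFVIEW = ReferenceView({"chr1": REF})


def truth_set(variants, regions=None):
    return TruthSet(
        variants=sorted(variants, key=lambda v: (v.contig, v.position)),
        confident_regions={"chr1": regions or [(0, len(REF))]},
    )


def make_site(position, alt_keys, ref_support=2, alt_support=2):
    """A SiteData with a reference candidate plus given (seq, span) alts."""
    candidates = [
        CandidateAllele(REF[position], 1, True, {f"p{position}ref{i}" for i in range(ref_support)})
    ]
    for k, key in enumerate(alt_keys):
        candidates.append(
            CandidateAllele(key[0], key[1], False, {f"p{position}alt{k}_{i}" for i in range(alt_support)})
        )
    reads = {rid: None for c in candidates for rid in c.support}
    return SiteData(
        contig="chr1",
        position=position,
        reference_context=REF,
        context_start=0,
        candidates=candidates,
        reads=reads,
    )


class TestFilterConfident:
    def make_spot(self, pos):
        return Hotspot("chr1", pos, {"C": 3}, 10)

    def test_inside_outside_and_boundary(self):
        truth = truth_set([], regions=[(900 - 800, 1100 - 800)])  # [100, 300)
        spots = [self.make_spot(150), self.make_spot(350), self.make_spot(299)]
        kept = filter_confident(spots, truth)
        assert [h.position for h in kept] == [150, 299]

    def test_unknown_contig_is_dropped_with_warning(self):
        truth = truth_set([])
        orphan = Hotspot("chrUn", 10, {"C": 3}, 10)
        with pytest.warns(UserWarning):
            assert filter_confident([orphan], truth) == []


class TestHaplotypePairs:
    def test_het_snv_gives_reference_and_alternate_windows(self):
        pos = 50
        v = TruthVariant("chr1", pos, REF[pos], ("C",), (0, 1))
        cluster = Cluster("chr1", [], [v], window_start=pos - 10, window_end=pos + 11)
        pairs = truth_haplotype_pairs(cluster, REFVIEW)
        window = REF[pos - 10 : pos + 11]
        with_alt = window[:10] + "C" + window[11:]
        assert pairs == [tuple(sorted((window, with_alt)))]

    def test_homozygous_deletion_alters_both_haplotypes(self):
        pos = 80
        ref_allele = REF[pos : pos + 4]
        v = TruthVariant("chr1", pos, ref_allele, (REF[pos],), (1, 1))
        cluster = Cluster("chr1", [], [v], window_start=pos - 8, window_end=pos + 12)
        (pair,) = truth_haplotype_pairs(cluster, REFVIEW)
        assert pair[0] == pair[1]
        assert len(pair[0]) == 20 - 3

    def test_two_unphased_hets_expand_to_cis_and_trans(self):
        p1, p2 = 120, 130
        v1 = TruthVariant("chr1", p1, REF[p1], ("A" if REF[p1] != "A" else "T",), (0, 1))
        v2 = TruthVariant("chr1", p2, REF[p2], ("G" if REF[p2] != "G" else "C",), (0, 1))
        cluster = Cluster("chr1", [], [v1, v2], window_start=p1 - 5, window_end=p2 + 6)
        pairs = truth_haplotype_pairs(cluster, REFVIEW)
        assert len(pairs) == 2  # cis (both on one hap) and trans (split)
        all_seqs = {s for pair in pairs for s in pair}
        assert len(all_seqs) == 4  # ref, alt1-only, alt2-only, both


class TestMatchCandidates:
    def run_cluster(self, sites, variants):
        clusters = cluster_sites(sites, truth_set(variants))
        assert len(clusters) == 1
        cluster = clusters[0]
        pairs = truth_haplotype_pairs(cluster, REFVIEW)
        return match_candidates(cluster, pairs, REFVIEW)

    def test_exact_alt_match_is_true_and_spurious_is_false(self):
        pos = 200
        alt = "C" if REF[pos] != "C" else "G"
        noise = "T" if REF[pos] not in ("T", alt) else "A"
        site = make_site(pos, [(alt, 1), (noise, 1)])
        labels = self.run_cluster(
            [site], [TruthVariant("chr1", pos, REF[pos], (alt,), (0, 1))]
        )
        assert labels[(pos, (alt, 1))] is True
        assert labels[(pos, (noise, 1))] is False
        assert labels[(pos, (REF[pos], 1))] is True  # het keeps the reference

    def test_homozygous_alt_leaves_reference_candidate_false(self):
        pos = 220
        alt = "C" if REF[pos] != "C" else "G"
        site = make_site(pos, [(alt, 1)])
        labels = self.run_cluster(
            [site], [TruthVariant("chr1", pos, REF[pos], (alt,), (1, 1))]
        )
        assert labels[(pos, (alt, 1))] is True
        assert labels[(pos, (REF[pos], 1))] is False

    def test_left_and_right_aligned_deletions_label_identically(self):
        # place the deletion inside a homopolymer so spellings differ
        run_start = 240
        window = REF[:run_start] + "AAAAAA" + REF[run_start + 6 :]
        refview = ReferenceView({"chr1": window})
        # truth written right-aligned: deletes the last two A's
        right = TruthVariant("chr1", run_start + 3, window[run_start + 3 :][:3], (window[run_start + 3],), (0, 1))
        # candidate spelled left-aligned at the run start (span 3 = anchor + 2 deleted)
        site = SiteData(
            contig="chr1",
            position=run_start,
            reference_context=window,
            context_start=0,
            candidates=[
                CandidateAllele(window[run_start], 1, True, {"r1"}),
                CandidateAllele(window[run_start], 3, False, {"r2"}),
            ],
            reads={"r1": None, "r2": None},
        )
        truth = TruthSet(variants=[right], confident_regions={"chr1": [(0, len(window))]})
        clusters = cluster_sites([site], truth)
        pairs = truth_haplotype_pairs(clusters[0], refview)
        labels = match_candidates(clusters[0], pairs, refview)
        assert labels[(run_start, (window[run_start], 3))] is True

    def test_no_matching_path_labels_everything_false(self):
        pos = 260
        alt = "C" if REF[pos] != "C" else "G"
        other = "T" if REF[pos] not in ("T", alt) else "A"
        site = make_site(pos, [(other, 1)])
        # truth requires `alt`, which no candidate provides, and is hom-alt,
        # so not even the reference path can match
        labels = self.run_cluster(
            [site], [TruthVariant("chr1", pos, REF[pos], (alt,), (1, 1))]
        )
        assert all(v is False for v in labels.values())


def brute_force_labels(cluster, pairs, refview):
    """Oracle: try every per-hotspot option assignment by string application."""
    window = refview.fetch(cluster.contig, cluster.window_start, cluster.window_end)
    window_start = max(cluster.window_start, 0)
    targets = {s for pair in pairs for s in pair}
    sites = sorted(cluster.sites, key=lambda s: s.position)
    labels = {
        (s.position, c.key()): False for s in sites for c in s.candidates
    }
    option_lists = []
    for s in sites:
        opts = [(c.key(), c.allele_sequence, c.ref_span) for c in s.candidates]
        if not any(c.is_reference for c in s.candidates):
            opts.append((None, window[s.position - window_start], 1))
        option_lists.append(opts)
    for combo in itertools.product(*option_lists):
        cursor = window_start
        built = []
        ok = True
        for s, (key, seq, span) in zip(sites, combo):
            if s.position < cursor:
                continue
            built.append(window[cursor - window_start : s.position - window_start])
            built.append(seq)
            cursor = s.position + span
        if not ok:
            continue
        built.append(window[cursor - window_start :])
        if "".join(built) in targets:
            for s, (key, _seq, _span) in zip(sites, combo):
                if key is not None:
                    labels[(s.position, key)] = True
    return labels


class TestOracleAgreement:
    def test_random_clusters_agree_with_string_application_oracle(self):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for trial in range(40):
            length = 120
            ref = "".join(rng.choice(list(bases), size=length))
            refview = ReferenceView({"chr1": ref})
            n_sites = int(rng.integers(1, 4))
            positions = sorted(
                rng.choice(np.arange(20, 90, 8), size=n_sites, replace=False).tolist()
            )
            sites = []
            variants = []
            for pos in positions:
                alts = []
                for _ in range(int(rng.integers(1, 3))):
                    if rng.random() < 0.5:
                        alt = bases[int(rng.integers(4))]
                        if alt != ref[pos]:
                            alts.append((alt, 1))
                    elif rng.random() < 0.5:
                        alts.append((ref[pos] + bases[int(rng.integers(4))], 1))
                    else:
                        alts.append((ref[pos], 1 + int(rng.integers(1, 4))))
                alts = list(dict.fromkeys(alts))
                if not alts:
                    continue
                cands = [CandidateAllele(ref[pos], 1, True, {f"{pos}r"})]
                cands += [
                    CandidateAllele(a[0], a[1], False, {f"{pos}a{i}"})
                    for i, a in enumerate(alts)
                ]
                sites.append(
                    SiteData("chr1", pos, ref, 0, cands, {r: None for c in cands for r in c.support})
                )
                if rng.random() < 0.8:  # most hotspots carry a truth variant
                    chosen = alts[int(rng.integers(len(alts)))]
                    seq, span = chosen
                    gt = (0, 1) if rng.random() < 0.6 else (1, 1)
                    variants.append(
                        TruthVariant("chr1", pos, ref[pos : pos + span], (seq,), gt)
                    )
            if not sites:
                continue
            truth = TruthSet(variants=variants, confident_regions={"chr1": [(0, length)]})
            for cluster in cluster_sites(sites, truth):
                pairs = truth_haplotype_pairs(cluster, refview)
                got = match_candidates(cluster, pairs, refview)
                want = brute_force_labels(cluster, pairs, refview)
                assert got == want, f"trial {trial} cluster at {cluster.window_start}"
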