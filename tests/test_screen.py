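import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import gotoh_local_score, scan_trace
from stemglobin.records import ProteinRecord
from stemglobin.screen import (
    KarlinParams,
    ScoredHit,
    ScreenError,
    build_concatemer_probe,
    evalue,
    iterate_until_stop,
    reciprocal_validate,
    screen_proteome,
    smith_waterman,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _identity_matrix(match=1.0, mismatch=-1.0):
    m = substitution_matrices.Array(alphabet=AAS + "X", dims=2)
    for a in AAS + "X":
        for b in AAS + "X":
            m[a, b] = match if (a == b and a != "X") else mismatch
    return m


def _rec(i, seq, species="sp"):
    return ProteinRecord(id=f"{species}|p{i}", species=species, sequence=seq)


class TestProbe:
    def test_single_sequence_identity(self):
        probe = build_concatemer_probe([_rec(1, "MVHL")])
        assert probe.sequence == "MVHL"
        assert probe.boundaries == ((0, 4),)

    def test_length_additivity_and_boundaries(self):
        probe = build_concatemer_probe([_rec(1, "MVH"), _rec(2, "ACDE")])
        assert len(probe) == 7
        assert probe.boundaries == ((0, 3), (3, 7))

    def test_twelve_distinct_references_keep_twelve_components(self):
        refs = [_rec(i, AAS[i:] + AAS[:i]) for i in range(12)]
        probe = build_concatemer_probe(refs)
        assert probe.n_components == 12

    def test_duplicate_sequences_collapse_to_distinct(self):
        # 19 genes but only 17 distinct sequences -> 17 probe components
        distinct = [AAS[i:] + AAS[:i] for i in range(17)]
        refs = [_rec(i, s) for i, s in enumerate(distinct + distinct[:2], start=1)]
        probe = build_concatemer_probe(refs)
        assert probe.n_components == 17

    def test_empty_input_rejected(self):
        with pytest.raises(ScreenError):
            build_concatemer_probe([])


class TestSmithWaterman:
    def test_self_alignment_identity_matrix(self):
        s, spans = smith_waterman("MVHLTPEEKS", "MVHLTPEEKS", matrix=_identity_matrix())
        assert s == 10
        assert spans == ((0, 10), (0, 10))

    def test_no_positive_pair_scores_zero(self):
        s, spans = smith_waterman("AAAA", "CCCC", matrix=_identity_matrix())
        assert s == 0
        assert spans is None

    def test_classic_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        s, _ = smith_waterman(a, b, gap_open=10, gap_extend=1)
        assert s == gotoh_local_score(a, b, gap_open=10, gap_extend=1)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(AAS), size=20))
            b = "".join(rng.choice(list(AAS), size=25))
            assert smith_waterman(a, b)[0] == smith_waterman(b, a)[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pairs_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            a = "".join(rng.choice(list(AAS), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list(AAS), size=int(rng.integers(5, 40))))
            assert smith_waterman(a, b)[0] == gotoh_local_score(a, b)

    def test_unknown_residue_goes_through_x_row(self):
        s, _ = smith_waterman("MVXHL", "MVXHL")
        assert s > 0  # never raises

    def test_empty_sequence_rejected(self):
        with pytest.raises(ScreenError):
            smith_waterman("", "ACD")


class TestEvalue:
    def test_closed_form(self):
        params = KarlinParams(lam=0.3, k=0.1, m=100, n=10_000)
        assert evalue(50, params) == pytest.approx(
            0.1 * 100 * 10_000 * math.exp(-15), rel=1e-12
        )

    def test_monotone_decreasing_in_score(self):
        params = KarlinParams(m=200, n=5_000)
        es = [evalue(s, params) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_large_score_limit(self):
        assert evalue(1e6, KarlinParams(m=100, n=100)) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_params_rejected(self):
        with pytest.raises(ScreenError):
            KarlinParams(lam=0.0)
        with pytest.raises(ScreenError):
            KarlinParams(k=-1.0)


class TestScreenProteome:
    def test_probe_components_hit_themselves(self):
        refs = [_rec(i, AAS * 3) for i in range(1, 2)] + [
            _rec(2, "".join(reversed(AAS)) * 3)
        ]
        probe = build_concatemer_probe(refs)
        hits = screen_proteome(probe, refs)
        assert {h.target_id for h in hits} == {r.id for r in refs}
        assert [h.rank for h in hits] == [1, 2]

    def test_pure_decoys_with_stringent_cutoff_may_be_empty(self):
        rng = np.random.default_rng(1)
        probe = build_concatemer_probe([_rec(0, "".join(rng.choice(list(AAS), 100)))])
        decoys = [
            _rec(i, "".join(rng.choice(list(AAS), 100))) for i in range(1, 15)
        ]
        hits = screen_proteome(probe, decoys, e_cutoff=1e-12)
        assert hits == []

    def test_matches_full_scan_oracle(self, default_truth):
        """Ranked output equals an independently-ordered exhaustive scan."""
        params = default_truth.params
        probe = build_concatemer_probe(
            [
                ProteinRecord(id=f"ref|{l}", species="ref", sequence=s)
                for l, s in sorted(default_truth.stem_sequences.items())
            ]
        )
        from stemglobin.simulate import make_decoys

        sp = "Platynereis"
        proteome = [
            ProteinRecord(id=g, species=sp, sequence=default_truth.core_sequences[g])
            for g in sorted(default_truth.clade_membership)
            if g.startswith(sp + "|")
        ] + [d for d in make_decoys(params, [sp])]
        e_cutoff = 10.0
        hits = screen_proteome(probe, proteome, e_cutoff=e_cutoff)
        # oracle: score everything, filter, sort with an independent key
        n_db = sum(len(r) for r in proteome)
        kp = KarlinParams(m=len(probe), n=n_db)
        scored = []
        for rec in proteome:
            s, _ = smith_waterman(probe.sequence, rec.sequence, with_spans=False)
            e = evalue(s, kp)
            if e <= e_cutoff:
                scored.append((e, -s, rec.id))
        scored.sort()
        assert [h.target_id for h in hits] == [x[2] for x in scored]
        assert [h.e for h in hits] == [x[0] for x in scored]


class TestReciprocalValidation:
    @pytest.fixture()
    def refdb(self, default_truth):
        refs = [
            ProteinRecord(id=f"ref|{l}", species="ref", sequence=s)
            for l, s in sorted(default_truth.stem_sequences.items())
        ]
        rng = np.random.default_rng(9)
        for k in range(4):
            refs.append(
                ProteinRecord(
                    id=f"ref|junk{k}",
                    species="ref",
                    sequence="".join(rng.choice(list(AAS), 150)),
                )
            )
        labels = {
            r.id: ("globin" if "junk" not in r.id else "non-globin") for r in refs
        }
        return refs, labels

    def test_exact_globin_match_validates(self, refdb):
        refs, labels = refdb
        hit = ProteinRecord(id="q|1", species="q", sequence=refs[0].sequence)
        ok, best = reciprocal_validate(hit, refs, labels)
        assert ok and best == refs[0].id

    def test_exact_decoy_match_fails(self, refdb):
        refs, labels = refdb
        junk = next(r for r in refs if "junk" in r.id)
        hit = ProteinRecord(id="q|2", species="q", sequence=junk.sequence)
        ok, best = reciprocal_validate(hit, refs, labels)
        assert not ok and best == junk.id

    def test_divergent_globin_agrees_with_exhaustive_ranking(self, refdb, default_truth):
        refs, labels = refdb
        gene = sorted(default_truth.clade_membership)[0]
        hit = ProteinRecord(
            id=gene, species="x", sequence=default_truth.core_sequences[gene]
        )
        ok, best = reciprocal_validate(hit, refs, labels)
        oracle_best = max(
            refs, key=lambda r: (smith_waterman(hit.sequence, r.sequence)[0], r.id)
        )
        assert best == oracle_best.id
        assert ok == (labels[oracle_best.id] == "globin")

    def test_needs_both_labels(self, refdb):
        refs, _ = refdb
        with pytest.raises(ScreenError):
            reciprocal_validate(refs[0], refs, {r.id: "globin" for r in refs})


class TestStoppingRule:
    @staticmethod
    def _run(outcomes, stop_n):
        hits = [
            ScoredHit(target_id=f"h{i}", species="s", score=100 - i, e=float(i), rank=i)
            for i in range(1, len(outcomes) + 1)
        ]
        lookup = {f"h{i}": ok for i, ok in enumerate(outcomes, start=1)}
        calls = iterate_until_stop(
            hits, lambda t: (lookup[t], "ref"), stop_n=stop_n
        )
        accepted_ranks = [int(a[1:]) for a in calls.accepted]
        return accepted_ranks, calls.stop_index

    def test_literal_rule(self):
        outcomes = [True, True] + [False] * 15
        accepted, stop = self._run(outcomes, stop_n=10)
        assert accepted == [1, 2]
        assert stop == 12

    def test_no_failure_run_scans_everything(self):
        outcomes = [True] * 8
        accepted, stop = self._run(outcomes, stop_n=10)
        assert accepted == list(range(1, 9))
        assert stop == 8

    def test_early_termination_skips_later_globin(self):
        outcomes = [True] + [False] * 9 + [True] + [False] * 10 + [True]
        accepted, stop = self._run(outcomes, stop_n=10)
        assert accepted == [1, 11]
        assert stop == 21  # the 22nd hit (a true globin) is never scanned

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scan_trace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        outcomes = (rng.random(60) < 0.35).tolist()
        stop_n = int(rng.integers(1, 12))
        accepted, stop = self._run(outcomes, stop_n=stop_n)
        oracle_accepted, oracle_stop = scan_trace(outcomes, stop_n)
        assert accepted == oracle_accepted
        assert stop == oracle_stop
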