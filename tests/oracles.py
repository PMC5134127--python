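"""Independent brute-force oracles used to validate the analysis engines.

The alignment oracle is a full Smith-Waterman (biotite's optimal local
aligner) with the same +1/-2 scoring and the same E-value convention as the
package's seed-and-extend engine; it shares no code with it.
"""

from __future__ import annotations

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from viroshare.homology import HomologyParams, evalue

_ALPH = bseq.NucleotideSequence.alphabet_unamb
_MATRIX = balign.SubstitutionMatrix(
    _ALPH, _ALPH, (np.full((4, 4), -2) + 3 * np.eye(4)).astype(np.int32)
)


def sw_best(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Optimal local alignment (score, alignment_columns, n_matches)."""
    alns = balign.align_optimal(
        bseq.NucleotideSequence(seq_a),
        bseq.NucleotideSequence(seq_b),
        _MATRIX,
        gap_penalty=(-5, -2),
        local=True,
        max_number=1,
    )
    aln = alns[0]
    n_cols = aln.trace.shape[0]
    if n_cols == 0:
        return 0, 0, 0
    identity = balign.get_sequence_identity(aln, mode="all")
    return int(aln.score), int(n_cols), int(round(identity * n_cols))


def oracle_pair_hit(
    query_seq: str, target_seq: str, database_length: int, params: HomologyParams
) -> bool:
    """Brute-force decision for one (query contig, target contig) pair."""
    score, n_cols, n_matches = sw_best(query_seq, target_seq)
    if n_cols == 0:
        return False
    return (
        n_cols >= params.min_alignment_length
        and n_matches / n_cols >= params.min_identity
        and evalue(score, len(query_seq), database_length, params)
        < params.evalue_threshold
    )


def oracle_contig_has_homologue(query_seq: str, target_seqs, params: HomologyParams) -> bool:
    """Brute-force virome-level decision: any target contig gives a passing hit.

    The E-value uses the total target length, matching the engine's
    database-size convention.
    """
    total = sum(len(t) for t in target_seqs)
    return any(oracle_pair_hit(query_seq, t, total, params) for t in target_seqs)
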