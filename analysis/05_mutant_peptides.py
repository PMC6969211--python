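#!/usr/bin/env python
"""Activation-loop peptides from the published mutagenesis primers.

The forward primers used to build the RSK1 S221D and RSK2 S227D
phosphomimetic mutants encode the mutated activation-loop peptide
directly; reverting the single mutated codon gives the wild-type peptide.
Both are classified with the S/T-x-x-G-T consensus engine: the wild-type
peptide carries the phosphorylatable site inside the consensus, the
mutant carries Asp there and no consensus match — exactly the situation
the alignment-column fallback exists for.
"""

from Bio.Seq import Seq

from agcphos.motifs import State, classify_residue

PRIMERS = {
    "RSK1_S221D_FW": "CCACGAGAAGAAGGCCTATGATTTCTGCGGGACAGTGG",
    "RSK2_S227D_FW": "CCATGAAAAGAAGGCATATGATTTTTGTGGAACTGTGG",
}


def consensus_position(peptide: str) -> int | None:
    for p in range(len(peptide) - 4):
        if peptide[p] in "ST" and peptide[p + 3] == "G" and peptide[p + 4] == "T":
            return p
    return None


def main() -> None:
    for name, primer in PRIMERS.items():
        # the mutated codon is the GAT (Asp) at the consensus position;
        # translation frame +1 skips the leading C of the primer
        frame = primer[1 : 1 + (len(primer) - 1) // 3 * 3]
        mutant = str(Seq(frame).translate()).rstrip("*")
        d_at = mutant.index("D")
        wild_type = mutant[:d_at] + "S" + mutant[d_at + 1 :]
        wt_pos = consensus_position(wild_type)
        print(f"{name}: {primer}")
        print(f"  mutant peptide    : {mutant}")
        print(f"  wild-type peptide : {wild_type}")
        assert wt_pos == d_at, "consensus site should sit at the mutated codon"
        print(
            f"  consensus S/T-x-x-G-T at peptide position {wt_pos + 1} "
            f"({wild_type[wt_pos:wt_pos + 5]}), state "
            f"{classify_residue(wild_type[wt_pos]).value}"
        )
        assert consensus_position(mutant) is None
        print(
            f"  mutant: consensus lost; residue {mutant[d_at]} classifies as "
            f"{classify_residue(mutant[d_at]).value}"
        )
        assert classify_residue(mutant[d_at]) is State.PHOSPHOMIMETIC
        print()


if __name__ == "__main__":
    main()
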