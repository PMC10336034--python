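"""Readers and writers: FASTA alignments, Newick trees, JSON/TSV reports."""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
from Bio import SeqIO

from .genetic_code import GeneticCode, get_code
from .likelihood import AlignmentError, CodonAlignment, PhyloTree, TreeError

__all__ = [
    "read_codon_alignment",
    "read_tree",
    "write_alignment_fasta",
    "write_tree",
]


def read_codon_alignment(path, mask_stops: bool = False,
                         code: GeneticCode | None = None) -> CodonAlignment:
    """Read an in-frame FASTA alignment into codon states.

    Rejects duplicate identifiers, unequal lengths, lengths not divisible by
    three, and unambiguous in-frame stop codons (unless ``mask_stops``
    replaces them with fully missing codons).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise AlignmentError(f"duplicate sequence identifier {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise AlignmentError(f"no sequences found in {path}")
    return CodonAlignment(sequences, code=code or get_code(),
                          mask_stops=mask_stops)


def read_tree(path, alignment: CodonAlignment | None = None,
              default_branch_length: float = 0.1) -> PhyloTree:
    """Read a Newick tree; leaf labels are matched case-sensitively.

    Branches without lengths default to ``default_branch_length`` with a
    warning. If an alignment is given, the leaf sets must match exactly and
    any offenders are listed.
    """
    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              preserve_underscores=True)
    if any(e.length is None for e in dtree.preorder_edge_iter()
           if e.head_node is not dtree.seed_node):
        warnings.warn(
            f"tree in {path} has branches without lengths; "
            f"defaulting to {default_branch_length}", UserWarning,
            stacklevel=2)
    tree = PhyloTree.from_dendropy(dtree, default_branch_length)
    if alignment is not None:
        tree_only = sorted(set(tree.leaf_names) - set(alignment.names))
        aln_only = sorted(set(alignment.names) - set(tree.leaf_names))
        if tree_only or aln_only:
            raise TreeError(
                "tree and alignment labels disagree; "
                f"tree-only={tree_only}, alignment-only={aln_only}")
    return tree


def write_alignment_fasta(alignment: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name in alignment.names:
            fh.write(f">{name}\n{alignment.sequence_string(name)}\n")


def write_tree(tree: PhyloTree, path, branch_lengths=None) -> None:
    Path(path).write_text(tree.to_newick(branch_lengths) + "\n")
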