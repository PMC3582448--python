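"""lincscan: classify long intergenic non-coding RNA vs protein-coding transcripts.

A small, fully offline toolkit: parse transcript annotations (BED/GTF/GFF3),
extract spliced sequences from a genome FASTA, average a per-base conservation
track over exons, compute ORF and k-mer features, train an RBF-kernel SVM with
grid search and cross-validation, and score transcripts with a calibrated
non-coding probability.  A synthetic corpus generator makes the whole pipeline
testable without external downloads.
"""

__version__ = "0.1.0"


class LincscanError(Exception):
    """Base class for all handled errors (bad input, bad config, bad files)."""


class ParseError(LincscanError):
    """A file could not be parsed; message names the file and line."""


class ValidationError(LincscanError):
    """Input parsed but violated a semantic constraint."""


class CoordinateError(LincscanError):
    """A genomic interval fell outside its chromosome."""


class ModelVersionError(LincscanError):
    """A persisted model carries an unknown format version."""
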