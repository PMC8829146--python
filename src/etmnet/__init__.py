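"""etmnet: miRNA-lncRNA-mRNA regulatory network construction.

Implements endogenous-target-mimic (eTM) detection by explicit pairing
rules, the tau tissue-specificity index, cis/trans lncRNA target
prediction, differential-expression threshold filtering, and assembly of
the resulting tripartite regulatory network, together with a synthetic
data generator that plants known signal for end-to-end validation.
"""

from importlib import resources

__version__ = "0.1.0"


def table1_fixture_path():
    """Path to the bundled published eTM pair table (TSV)."""
    return resources.files("etmnet.data") / "table1_etm_pairs.tsv"
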