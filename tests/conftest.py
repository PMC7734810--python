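import pytest

from slrscreen.corpus import Citation, ExclusionReason, Label, LabelScheme, LabelledDataset

R = ExclusionReason


def make_citation(i, abstract="alpha beta gamma", abs_dec="exclude",
                  abs_reason=R.POPULATION, ft_dec="not_screened", ft_reason=None,
                  title="", tag="fix"):
    return Citation(
        id=f"c{i:02d}",
        title=title,
        abstract=abstract,
        abstract_decision=abs_dec,
        abstract_reason=abs_reason if abs_dec == "exclude" else None,
        fulltext_decision=ft_dec,
        fulltext_reason=ft_reason,
        dataset_tag=tag,
    )


@pytest.fixture
def ten_citations():
    """Ten records: 3 abstract includes, of which 1 survives full text.

    The two over-included records were excluded at full text for
    population and outcomes; the seven abstract excludes span several
    reasons (two of them for time, to exercise recoding).
    """
    return [
        make_citation(0, "randomized adults psoriasis trial", "include",
                      ft_dec="include"),
        make_citation(1, "children cohort psoriasis", "include",
                      ft_dec="exclude", ft_reason=R.POPULATION),
        make_citation(2, "surrogate endpoints only", "include",
                      ft_dec="exclude", ft_reason=R.OUTCOMES),
        make_citation(3, "mouse model skin", abs_reason=R.POPULATION),
        make_citation(4, "case report single patient", abs_reason=R.STUDY_DESIGN),
        make_citation(5, "editorial comment letter", abs_reason=R.STUDY_DESIGN),
        make_citation(6, "wrong drug comparator arm", abs_reason=R.COMPARATOR),
        make_citation(7, "short followup four weeks", abs_reason=R.TIME),
        make_citation(8, "followup too brief", abs_reason=R.TIME),
        make_citation(9, "protocol only registry entry", abs_reason=R.OTHER),
    ]


@pytest.fixture
def ten_dataset(ten_citations):
    from slrscreen.corpus import derive_labels

    return derive_labels(ten_citations, LabelScheme.ABSTRACT)
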