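import io
import textwrap

import numpy as np
import pytest

import seqdiv as sd

#: minimal molecular-function ontology: a chain, a diamond, a second branch,
#: one foreign-namespace term and one obsolete term
TOY_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: go

    [Term]
    id: GO:0000001
    name: root
    namespace: molecular_function

    [Term]
    id: GO:0000002
    name: mid
    namespace: molecular_function
    is_a: GO:0000001 ! root

    [Term]
    id: GO:0000003
    name: leaf
    namespace: molecular_function
    is_a: GO:0000002 ! mid

    [Term]
    id: GO:0000004
    name: branch
    namespace: molecular_function
    is_a: GO:0000001 ! root

    [Term]
    id: GO:0000005
    name: diamond-bottom
    namespace: molecular_function
    is_a: GO:0000002 ! mid
    is_a: GO:0000004 ! branch

    [Term]
    id: GO:0000009
    name: elsewhere
    namespace: biological_process

    [Term]
    id: GO:0000010
    name: retired
    namespace: molecular_function
    is_obsolete: true
    """
)


@pytest.fixture
def toy_go():
    return sd.load_obo(io.StringIO(TOY_OBO))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_fragment(bits, rank=1, symbols=None, subject_id=None):
    """Hand-build an aligned fragment from a bit string like '11100'."""
    bit_arr = np.array([int(b) for b in bits], dtype=np.uint8)
    if symbols is None:
        symbols = "".join("A" if b else "." for b in bit_arr)
    return sd.AlignedFragment(
        subject_id=subject_id or f"f{rank}",
        symbols=symbols,
        bits=bit_arr,
        original_rank=rank,
        score=100.0 - rank,
        evalue=1e-6,
        qstart=1,
        qend=int(bit_arr.sum()) or 1,
    )


@pytest.fixture
def fig2_rows():
    """Four 13-column rows whose column compositions reproduce the worked
    entropy example: column 1 is three G and a gap, column 3 is half S,
    column 10 is all A."""
    return [
        "GKSWWNDYLAVHG",
        "GKSYWNEYLAKHG",
        "GHAFWNDYLAVHG",
        "-HAYWQEYLAKHG",
    ]


def blast_xml_hsp(num, qfrom, qto, qseq, hseq, bits=50.0, evalue=1e-10,
                  include_seqs=True):
    seqs = (
        f"<Hsp_qseq>{qseq}</Hsp_qseq><Hsp_hseq>{hseq}</Hsp_hseq>"
        if include_seqs
        else ""
    )
    return (
        f"<Hsp><Hsp_num>{num}</Hsp_num><Hsp_bit-score>{bits}</Hsp_bit-score>"
        f"<Hsp_score>120</Hsp_score><Hsp_evalue>{evalue}</Hsp_evalue>"
        f"<Hsp_query-from>{qfrom}</Hsp_query-from><Hsp_query-to>{qto}</Hsp_query-to>"
        f"<Hsp_hit-from>1</Hsp_hit-from><Hsp_hit-to>{qto - qfrom + 1}</Hsp_hit-to>"
        f"<Hsp_identity>1</Hsp_identity><Hsp_positive>1</Hsp_positive>"
        f"<Hsp_align-len>{len(qseq)}</Hsp_align-len>"
        f"{seqs}<Hsp_midline>{' ' * len(qseq) if include_seqs else ''}</Hsp_midline></Hsp>"
    )


def blast_xml_hit(num, hit_id, hsps):
    return (
        f"<Hit><Hit_num>{num}</Hit_num><Hit_id>{hit_id}</Hit_id>"
        f"<Hit_def>d</Hit_def><Hit_accession>a</Hit_accession>"
        f"<Hit_len>50</Hit_len><Hit_hsps>{hsps}</Hit_hsps></Hit>"
    )


def blast_xml_report(hits, query_len=10):
    return textwrap.dedent(
        f"""\
        <?xml version="1.0"?>
        <!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
        <BlastOutput>
        <BlastOutput_program>blastp</BlastOutput_program>
        <BlastOutput_version>BLASTP 2.12.0+</BlastOutput_version>
        <BlastOutput_reference>r</BlastOutput_reference>
        <BlastOutput_db>db</BlastOutput_db>
        <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
        <BlastOutput_query-def>q</BlastOutput_query-def>
        <BlastOutput_query-len>{query_len}</BlastOutput_query-len>
        <BlastOutput_param><Parameters>
        <Parameters_matrix>BLOSUM62</Parameters_matrix>
        <Parameters_expect>10</Parameters_expect>
        <Parameters_gap-open>11</Parameters_gap-open>
        <Parameters_gap-extend>1</Parameters_gap-extend>
        <Parameters_filter>F</Parameters_filter>
        </Parameters></BlastOutput_param>
        <BlastOutput_iterations><Iteration>
        <Iteration_iter-num>1</Iteration_iter-num>
        <Iteration_hits>{hits}</Iteration_hits>
        </Iteration></BlastOutput_iterations>
        </BlastOutput>
        """
    )


@pytest.fixture
def random_star(rng):
    def build(max_fragments=15, max_length=40):
        query, hits = sd.random_fixture(
            rng, max_fragments=max_fragments, max_length=max_length
        )
        return sd.build_star_alignment(query, hits)

    return build
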