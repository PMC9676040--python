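import pytest

from chromcensus.io import BlastTabRecord, DomtblRecord, ProteinRecord


def make_hsp(qseqid="q1", sseqid="s1", qstart=1, qend=100, sstart=1, send=100,
             evalue=1e-20, strand="+", **kw):
    defaults = dict(pident=80.0, aln_len=qend - qstart + 1, mismatch=0, gapopen=0,
                    bitscore=200.0)
    defaults.update(kw)
    return BlastTabRecord(qseqid=qseqid, sseqid=sseqid, qstart=qstart, qend=qend,
                          sstart=sstart, send=send, evalue=evalue, strand=strand,
                          **defaults)


def make_domhit(target="p1", target_len=200, domain="PF00856", hmm_len=130,
                hmm_from=1, hmm_to=130, env_from=10, env_to=139, i_evalue=1e-20):
    return DomtblRecord(target_id=target, target_len=target_len, domain_id=domain,
                        hmm_len=hmm_len, i_evalue=i_evalue, hmm_from=hmm_from,
                        hmm_to=hmm_to, env_from=env_from, env_to=env_to)


@pytest.fixture
def h3():
    from chromcensus.histone import DEFAULT_HISTONES

    return ProteinRecord("H3", "H3", DEFAULT_HISTONES["H3"])


@pytest.fixture
def h4():
    from chromcensus.histone import DEFAULT_HISTONES

    return ProteinRecord("H4", "H4", DEFAULT_HISTONES["H4"])
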