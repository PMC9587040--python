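import pytest

from srs_signal.jader_io import CaseBundle, DemoRecord, DrugRecord, ReacRecord


@pytest.fixture
def make_bundle():
    """Factory for hand-built report bundles with sensible defaults."""
    def _make(case_id, sex="female", age_band="60-69",
              height_band="160-169", weight_band="50-59",
              drugs=(), reactions=()):
        demo = DemoRecord(case_id, sex, age_band, height_band, weight_band)
        drug_records = [
            DrugRecord(case_id, d.get("drug_name", "drugA"),
                       d.get("role", "suspected"),
                       d.get("start_date", ""), d.get("end_date", ""))
            for d in drugs]
        reac_records = [
            ReacRecord(case_id, r.get("pt_code", "10056979"),
                       r.get("pt_name", "target event"),
                       r.get("onset_date", ""), r.get("outcome"))
            for r in reactions]
        return CaseBundle(demo, drug_records, reac_records)
    return _make
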