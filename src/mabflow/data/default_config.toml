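# Default pipeline configuration: every shared parameter lives here, once.
# Paths are relative to the invocation root (--root / current directory).

[general]
barcode_pad_width = 3
scan_order = "row-major"
quadrant_convention = "interleaved"
user = "mabflow"

[paths]
input_dir = "00_Input"
log_dir = "logs"
store_list_dir = "store_lists"

[headers]
electrophoresis = ["sample_id", "plate_barcode", "well", "chain", "band_size_bp"]
quantification = ["sample_id", "plate_barcode", "well", "concentration_ng_ul"]
store_list = ["sample_id", "plate_barcode", "well", "enqueued_at"]
allele_calls = ["sample_id", "chain", "v_allele", "j_allele", "evaluation", "plate_barcode", "well"]
worklist = ["source_barcode", "source_well", "dest_barcode", "dest_well", "volume_ul"]
transfection_layout = ["plate_barcode", "well", "heavy_plasmid_id", "light_plasmid_id"]
seq2_results = ["sample_id", "status"]

[steps.traf]
number = 0
barcode_prefix = "TRAF_"
plate_format = 96

[steps.quant]
number = 1
plate_format = 96

[steps.pcr3]
number = 5
batch_size = 96
barcode_prefix = "PCR3_"
plate_format = 96
volume_ul = 5.0

[steps.cele2]
number = 6
# illustrative amplicon-size window; set per assay
min_band_bp = 300.0

[steps.gias]
number = 7
batch_size = 96
barcode_prefix = "GiAs_"
plate_format = 96
volume_ul = 10.0

[steps.pla]
number = 8
max_picks = 3

[steps.mini]
number = 9

[steps.concadj]
number = 10
target_ng_ul = 50.0
final_volume_ul = 20.0

[steps.repick]
number = 13
max_picks = 3
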