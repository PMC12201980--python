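label,basis,delta,polarity,diagnostic_class
W,SPB,-H2O,+,ceramide
W-H2O,SPB,-H2O-H2O,+,ceramide
W-2H2O,SPB,-H2O-H2O-H2O,+,ceramide
V,FA,+C2H5N-H2O,+,ceramide
V-H2O,FA,+C2H5N-H2O-H2O,+,ceramide
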