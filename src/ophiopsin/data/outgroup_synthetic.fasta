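>Mel_receptor_like_synthetic
TNPHDYYHPGPHQGNKPDYKSNYNDHRPWFFVILIIAFVFALWFWFMLVFLFSSNSSQST
PKGNRGRYEDPYSPYAFFLAWAIIFFFVVVWWVFLAASSQPRQKNQNDEYGEQGQTDIVI
LWWWFLVIFLAAAVAWIIWFHRKSHRYPSQEHGDEKIWLFAVLIMFWMMIMFLWVMIILF
PNKSHKTSHNEHDRHNSGHEHLAWLWFLVIAMIIMFFAVVAVFVWPNSSDSKRRYPQQRQ
RKEGEHHLWFWFVAVIMALIVAVVMFMAMHYNRNDEERKDGYEEQKQDNNDRQSTSRKWV
LVAIILIAVVWLVVVMWIWAIIKQSGGEHPKGKNKNQYNKST
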