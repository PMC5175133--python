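sample_id,group,gene,ct_target,ct_reference
cont00,control,DEPDC1B,25.017096383626594,20.0
cont01,control,DEPDC1B,25.67987377015498,20.0
cont02,control,DEPDC1B,25.612360539292965,20.0
cont03,control,DEPDC1B,24.744846461606166,20.0
cont04,control,DEPDC1B,24.851015244446778,20.0
cont05,control,DEPDC1B,24.736307903483286,20.0
cont06,control,DEPDC1B,25.28486317878598,20.0
cont07,control,DEPDC1B,24.971967780477193,20.0
case00,case,DEPDC1B,22.87344280812827,20.0
case01,case,DEPDC1B,21.576337600512947,20.0
case02,case,DEPDC1B,23.28327438734976,20.0
case03,case,DEPDC1B,22.45178391992219,20.0
case04,case,DEPDC1B,22.840189226637072,20.0
case05,case,DEPDC1B,22.431716833011585,20.0
case06,case,DEPDC1B,22.310450716462572,20.0
case07,case,DEPDC1B,22.731555079298793,20.0
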