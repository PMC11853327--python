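code,pt_name,condition
10059866,Drug resistance,resistance
10048723,Multiple drug resistance,resistance
10013709,Drug ineffective,ineffectiveness
10083365,Drug effect less than expected,ineffectiveness
10082201,Therapeutic product effect decreased,ineffectiveness
10082200,Therapeutic product effect incomplete,ineffectiveness
10060769,Therapeutic product ineffective,ineffectiveness
10043414,Therapeutic response decreased,ineffectiveness
10078575,Therapeutic response shortened,ineffectiveness
10051082,Therapy non-responder,ineffectiveness
10078115,Therapy partial responder,ineffectiveness
10066901,Treatment failure,ineffectiveness
10011953,Decreased activity,ineffectiveness
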