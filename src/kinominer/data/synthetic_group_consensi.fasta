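>AGC synthetic consensus domain
TNPYQWKMVRNISAMMAEHGHWDKVFNCMIFQHRAYCYWAENLVMQQESTQRHWQQEFFS
FFVAGILLMQDWNMIHANVAPAQCCYGWIKYFWNALQISWMDPCHWGTVAWNCHKNASFR
>CAMK synthetic consensus domain
TNPYLWHFVLNYHPDMVCQGLWSNMFYQSWQHNWAYAVTWSELCMFNSAFQKYFENLRIM
YYVATSMQDQTHLRPFARSSHCGCINQWAWNQWLALQIEWSDCCATFTWAWRWNMKFHRG
>CMGC synthetic consensus domain
TNPELWVKYGFYSYAMPYWGGYEFMINTMMIPHGARAPHASGLRMPQESTQRGAQNERYG
SKVIGQFQDQTRLKIDAGTDFQGMGEGWANMQWLANYIEESQYCHDFVCAWNAGMNIEHQ
>CK1 synthetic consensus domain
CCNYQHHKVVFLSYGDPYFGHWDFSANRMEMKVGFYSPYAEELDAFVWSRQRYAQYMRQA
IKDAGYNRDIAPCRIRTVKPWQTMGPGIHPSDILAKQIEQSFPCHWFPCCWNCSLGIGHQ
>RGC synthetic consensus domain
NLCYKWNKFRNYSPMYRGYVSHRYMCNAMMSPHGAYAVHAEHLRMFDKSTQNGSQNYRMG
WCVAPIFDDDAPLLIHANMSPWVMGEGGAPSAWRAGQIEIMMPCDWWTIARWSYMNIEHI
>TK synthetic consensus domain
IAPGQVIKVLCYNPMMYGYQYMVQMLNNMQQWHGAYAPFSFELAMWLVMTSRFNQNEWYG
AKPFPEFVHDTVFFPHNVNSDNHMGEEWAPSQSIGEQIEWLCPCHWFEPAIVRHMEIENK
>TKL synthetic consensus domain
ANPSQWHPIIDYQDPVPEQNHWDQMANTGKQPNIAYAPSARELYMFPRSEVCQCQNECAD
FADAYYSRDIHPLTIHHNSKAAGMGPGWKPSHMLQLQREWSDMLEWFMCDWTWHMNNYIW
>STE synthetic consensus domain
MNPSQWIKVLMAYPMMPPDGDCDQMANTMYPNHGAYCPTYEELRSFQDSTSRIYMNERKD
MWVAFYFYVQTPLWINLNFSPRGMGEMKAPSSWLASQYESMEPCHWFTCGTKWRFNWNHI
>Other synthetic consensus domain
EPDYQWHLGLNYSPVRPGCPIYIQMCLTASNPHIAYPVHPMELYMYQESQQRCVQNECYE
INVLNQFYSQYILRIGAARPPRGMGQEWRLCLWYLLQIQWSDPAMWCEPAWYWDMNPEHI
>aPK synthetic consensus domain
FNPNQFHKRTCYLIMYPGWGTWDGMANTMLYPRVNLAPHCDWLRMFQHSTQRNFPKESCW
FKVAGGFESQRPPRIHAMRPPQGMFKQWGPHQFLALQWYSSVPCHSPTCAWNWKMNIEHI
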