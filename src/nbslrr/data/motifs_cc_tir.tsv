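family_context	region	name	motif_number	consensus	printed_length	e_value
CC	N-terminal	C1	Motif10	xxaVkxWvxkLxdxxYe/dad/eDLLDExsYExLRRxVxxxxx	39	3.0e-183
CC	N-terminal	C2	Motif20	ntKqVRIFFSKSNQiaFrxK/rMxxkiKxi/vrEkLDaIxxe/dKtqfhLxxxxre	50	1.5e-090
CC	N-terminal	C3	Motif16	xxxxxxxxETxSf/si/llexeViGRe/dxe/dv/kxxIvxxl/vlDxsxxe	40	1.7e-121
CC	NBS	P-loop	Motif01	xxIxGmGGxGKItLAkxxxxx	21	1.5e-278
CC	NBS	RNBS-A-nonTIR	Motif06	xFdxxiwVcVSxxFdxxxIlx	21	6.1e-201
CC	NBS	Kinase-2	Motif03	gKkYf/lLVl/mDDVWNexxxlWxxLKxxLmxx	29	2.9e-255
CC	NBS	RNBS-B	Motif14	xxGs/nxIlvTTRSxxvaxxxxt	21	7.4e-153
CC	NBS	RNBS-C	Motif11	hxlxxLxxxxswxlFxxxaxx	21	1.1e-180
CC	NBS	GLPL	Motif08	xexvxxxxGxPLaxxxxGxxl	21	2.9e-195
CC	NBS	RNBS-D-nonTIR	Motif02	xxxxlKxCFxyCSxFPkDxxi/f	21	6.5e-234
CC	NBS	CNBS-1	Motif15	xkxxLIxxWmAqGFiqxxxxx	21	1.2e-144
CC	NBS	CNBS-2	Motif09	xmEdi/vGe/dxYFxeLlsRxl/fFqdxxxxxxxx	29	4.5e-195
CC	NBS	MHDV	Motif05	xxKMHDlxh/rDxAxxixxxxxx	21	3.0e-213
CC	LRR&C-terminal	L1	Motif17	lpxxixxLxhLryLdxsxx	19	8.7e-118
CC	LRR&C-terminal	L2	Motif04	LPxxixxLxxLxxLxlxxCxxLxxlPxxx	29	1.1e-250
CC	LRR&C-terminal	L3	Motif07	TLsxFvxGfxkGxki/lxELxxLxnLkGxLxlxxLexvx	37	4.6e-198
CC	LRR&C-terminal	L4	Motif13	xxxxxDxxVLEGLqPHxNlxxlxIxxf/yxG	29	2.8e-171
CC	LRR&C-terminal	L5	Motif12	pxxxFVENLVxIxLxxCxxcExLPmlgqL	29	6.6e-156
CC	LRR&C-terminal	L6	Motif18	xxxxxxxxxxfxxLxxlxixxCxxLxxxp	29	3.8e-095
CC	LRR&C-terminal	L7	Motif19	xxFPxLkxl/fxixxmxnLexWw	21	2.8e-108
TIR	N-terminal	T1	Motif03	sxxxwxYDVFLSFRGeDTRxnFtxhLxxALrxxGi/vnvFi/rDx	41	1.1e-238
TIR	N-terminal	T2	Motif06	CLxELVKIxxCkkxxxQxVLPv/iFYkv/iDPSxVRKQx	35	2.8e-187
TIR	N-terminal	T3	Motif13	xxkvqxWRxAl/mtxa/vanlsGWxlxxxxxex	29	5.4e-095
TIR	N-terminal	T4	Motif18	xIsxxLxkxIxxSxxsiVi/vfSexYAsSxW	29	4.7e-090
TIR	NBS	P-loop	Motif01	xGm/iGGIGKTTl/iAKalYnxixxxFexcCFL	29	3.6e-378
TIR	NBS	RNBS-A-TIR	Motif15	gLvxLQxxLLxxilx	15	1.5e-082
TIR	NBS	RNBS-B	Motif02	gxdWFGxGSr/kiIxTTRnxhLLxxxxf	26	2.4e-294
TIR	NBS	Kinase-2	Motif05	iIr/kxRLxxKKvLiv/iLDDVDxxxQLxaLa/rG	29	1.8e-261
TIR	NBS	RNBS-C	Motif07	iLFLFSwHAFxxxhPsxxYld	21	4.7e-178
TIR	NBS	GLPL	Motif04	avxYckGLPLALxvLGSfLxx	21	7.1e-205
TIR	NBS	RNBS-D-TIR	Motif09	keIFIdIsCxFvGexxxxvxxxl	23	1.5e-138
TIR	NBS	TNBS-1	Motif16	xlxxxixxxLxiSy/fdgLexxx	21	1.2e-087
TIR	NBS	MHDL	Motif08	Xxxxr/kxxMHdLIqxMGxxIvx	21	1.0e-160
TIR	LRR&C-terminal	L1	Motif19	xxxkrsRLWlxxdxxxxlxxxxgxxxxxxix	31	4.1e-073
TIR	LRR&C-terminal	L2	Motif20	S/pxxLRwxnWhGf/yPxxxLPxxfxmxxLxeLxLpxSxixxfw	40	3.9e-066
TIR	LRR&C-terminal	L3	Motif10	LxxxPDl/fSxaxNLexLxLxxCxxLxxxHxSv/igsL	34	9.8e-178
TIR	LRR&C-terminal	L4	Motif14	lxlxxcxnlxxlPSxLxLKSLxxLxlxxCxkxExxPxfxenMKSLxxlxl	50	7.7e-092
TIR	LRR&C-terminal	L5	Motif12	xtxixxLxxSIxxLxxLxxLxlxxCxxLxxLPxxIxxLxsL	41	1.8e-144
TIR	LRR&C-terminal	L6	Motif17	TxLxLxxCn/kIt/sNxdFLEtlxxvapsLxxLxLSxNxFc/sxLPS	41	4.6e-082
TIR	LRR&C-terminal	L7	Motif11	l/ixxf/lxsLxxLlxnCxLxxIpklPxxlxxxxaxgx	36	3.3e-136
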